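# Methods

## The model

`cellprs` estimates the effect of an exposure trait's genetic score on an
outcome trait from two independent GWAS summary-statistic sets.  For SNP
*j*, let *w_j* be the exposure effect per dose of the coded allele (the
score weight), and *(b_j, s_j)* the outcome effect and its standard error
for the same coded allele.  The score regression ("gtx", equivalently the
IVW estimator of two-sample Mendelian randomization) is the no-intercept
weighted least-squares fit of *b* on *w* with weights 1/s²:

    α̂  = Σ w_j b_j / s_j²  ÷  Σ w_j² / s_j²
    se  = (Σ w_j² / s_j²)^(−1/2)
    χ²  = (α̂/se)²,   p = P(χ²₁ ≥ χ²)
    pseudo-R² = 1 − exp(−χ²/n)

The pseudo-R² is the likelihood-ratio form for a quadratic log-likelihood
at outcome sample size *n*; the first-order variant χ²/n is available via
`RunConfig.pseudo_r2_form="linear"`.  The estimator is exact when SNPs are
uncorrelated, which is why the pipeline feeds it only clumped variants.
No intercept and no overdispersion scaling are used (the plain
fixed-effect form), and deliberately no instrument-strength threshold or
pleiotropy-robust variant: the method is a risk-score regression, not a
causal estimator.

Under the fixed-effect model the α̂ of any SNP subset estimates the same
α.  Two consequences matter for interpretation and are exploited by the
inference layer:

* **Nested variance identity.**  For a full instrument and the complement
  obtained by removing a subset, the precisions add:
  1/se²_full = 1/se²_complement + 1/se²_removed, hence
  var(α̂_full − α̂_complement) = se²_complement − se²_full.  The
  leave-set-out attenuation z-statistic divides the difference of the two
  fits by the square root of that quantity.
* **Subset invariance and the permutation statistic.**  Because every
  subset estimates the same α, a set-size-matched permutation null on
  |α̂| is correctly calibrated but has power only against *heterogeneity*
  of α across sets.  When the signal of interest is a *concentration* of
  exposure effect mass (the planted-simulation design, where the outcome
  depends on the exposure score as a whole), the discriminating statistic
  is the standardized association |α̂|/se, which credits the concentrated
  set's precision.  `permutation_null` therefore supports both:
  `statistic="abs_alpha"` (the default for the standalone operation) and
  `statistic="abs_z"` (the pipeline default, `RunConfig.perm_statistic`).
  Both are exchangeable-null calibrated; the choice only affects power.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| `maf_min` | 0.01 | variants with MAF strictly below are excluded |
| `info_min` | 0.9 | variants with imputation INFO strictly below are excluded |
| `clump_window_kb` | 10,000 | clumping window, ± from the index SNP (bp = kb×1000) |
| `clump_r2_max` | 0.001 | reference-panel r² above which a neighbour is absorbed |
| `excluded_regions` | APOE chr19:44,500,000–46,000,000; MHC chr6:26,000,000–34,000,000 | closed intervals removed from the pruned pool |
| `upstream_bp` / `downstream_bp` | 2,000 / 500 | strand-aware gene proximity window (5′/3′) |
| `p_thresholds` | 0.01, 0.5, 1.0 | exposure-p inclusion thresholds (strict `<`) |
| `n_perm` | 1,000 | permuted SNP sets per permutation null |
| `fwe_alpha` | 0.05 | family-wise error level (Bonferroni; Holm optional) |

Conventions that required a decision:

* Coordinates are 1-based inclusive internally; BED inputs are converted
  on read.  Region bounds given in kb are kb×1000 bp, inclusive at both
  ends.  Filter thresholds *keep* values equal to the threshold (the
  exclusion rules are strict `<`).
* Clumping is greedy by ascending exposure p, ties broken by smaller
  (chromosome, position), so results are independent of input row order.
  SNPs absent from the LD reference are treated as uncorrelated and
  retained with a warning (the permissive behaviour; `missing_ld_policy=
  "drop"` removes them instead).  Region exclusion runs *after* clumping —
  regions are removed from the pruned pool — so the APOE sensitivity
  comparison can re-include the same clumped region SNPs without
  re-clumping.
* Threshold comparison is strict, so at threshold 1.0 a pair with exposure
  p exactly 1.0 is excluded — a documented boundary.
* One SNP per gene: per gene the smallest-exposure-p SNP is kept (tie:
  smaller position); a SNP still claimed by several genes goes to the
  nearest gene body (tie: smaller gene start).  A SNP whose gene is a
  marker of several cell types counts in each of their sets.
* Palindromic (A/T, C/G) pairs are kept and flagged by default — the
  synthetic universe has a single strand convention — with a drop policy
  available.
* Allele harmonization negates the outcome beta when the coded/other
  alleles are swapped and drops pairs whose allele sets differ entirely.
* The FWE family is the (cell types × thresholds) tests actually
  performed; skipped empty instruments do not count, and the whole-genome
  score is reported alongside but not counted in the family.
* The permutation pool is the gene-mapped SNP universe restricted to the
  target's p-threshold, so the null is matched for set size and threshold.
  The observed set may be re-drawn by chance; draws are without
  replacement within each set.
* Marker enrichment: expression is scaled to integer pseudo-counts
  (`count_scale`, default 100 per expression unit) and each gene's counts
  in a cell-type column are tested against its counts in the background
  column by the upper-tail cumulative hypergeometric (the standard
  2-column contingency form, one-sided); BH-FDR is applied across genes
  within each cell type, and markers additionally require log2 fold change
  over background > 0 (pseudocount 1e-9 of the table mean).  This is one
  concrete realization of "cumulative hypergeometric testing" on a
  mean-expression table; it defines a proper per-gene tail probability,
  which a top-expression-bin membership rule does not.

## The synthetic study

The generator emulates the study design, not any particular dataset:

* **Genome.**  600 genes (10 kb long, 2 Mb apart) on four autosomes, ~5%
  non-protein-coding; 3,000 SNPs placed in gene bodies plus planted
  decoys: 30 low-MAF, 30 low-INFO (genic, so they are removed by QC and
  not by mapping), 20 APOE-region and 20 MHC-region SNPs, 60 intergenic
  SNPs beyond every window, and 30 SNPs in deliberately overlapping
  windows of squeezed gene pairs (multi-gene mapping).  Gene MAFs are
  U(0.05, 0.5); INFO U(0.92, 1.0) with decoys U(0.5, 0.89).
* **LD.**  200 blocks of 3 SNPs at r = 0.9, block members sharing one MAF.
  Within a block every non-seed gamete copies the seed's allele with
  probability r, else draws fresh — so the configured r is the
  seed–member allele correlation (≈ the dosage correlation).  A
  latent-Gaussian threshold scheme was rejected because tetrachoric
  attenuation makes the realized dosage correlation substantially smaller
  than the configured r (at MAF 0.5, latent r = 0.95 yields dosage
  r² ≈ 0.64).  Blocks are independent of each other; there is no
  long-range or cross-chromosome LD, which is all clumping correctness
  requires.
* **Effects.**  A fraction `frac_causal` = 0.2 of genic SNPs is causal
  with standardized effects N(0, 1), inflated to N(0, enrichment) = N(0, 5)
  for SNPs in target-cell-type genes (smooth muscle cells by default).
  APOE-region decoys are always causal with N(0, 25) effects, mimicking a
  large-effect locus; MHC decoys are never causal.  Per-dose weights are
  the standardized effects divided by √(2p(1−p)).
* **Phenotypes.**  The genetic score G = Σ w·dose is standardized; the
  exposure liability is √h²·G + √(1−h²)·ε with h² = 0.5; the outcome is
  α·G + √(1−α²)·ε with α = 0.3, standardized.  Case-control liability
  thresholds, covariates, population structure and relatedness are *not*
  simulated — the proportional-effect target is invariant to the first
  and the rest are out of scope — so passing tests demonstrate estimator
  and pipeline correctness under the stated model, not robustness to
  real-data pathologies (stratification, sample overlap, strand
  ambiguity, heterogeneous pleiotropy).
* **Cohorts.**  The exposure GWAS comes from its own 20,000-individual
  cohort (two-sample design, no overlap); the outcome cohort (20,000) is
  split 2:1 into discovery and replication by simple random assignment
  (no covariate matching); an independent 2,504-individual panel provides
  LD, the size of a phase-3 reference panel.  GWAS are marginal per-SNP
  OLS fits with intercept; p-values use the t distribution with n−2 df.

With a finite reference panel, "independent" SNP pairs have E[r̂²] ≈ 1/n_ref
≈ 4×10⁻⁴, and at the r² ≤ 0.001 default a sizeable share of null pairs
exceeds the threshold inside the very wide ±10 Mb window; the clumped pool
therefore shrinks well below the QC'd count (≈ 1,000 of ≈ 2,950 at the
default scale) exactly as aggressive clumping does in practice.  Causal
SNPs, having the smallest p-values, are processed first and survive
preferentially.

## Experiment sizes

Chosen so the whole suite replays comfortably on a single CPU:

* Estimator-vs-WLS exactness: 100 random instances, agreement to 1e-10.
* Individual-level equivalence: one study at 20,000 × 3,000.
* Calibration: 1,000 null and 1,000 effect replicates at n_outcome = 2,000,
  300 SNPs, no LD.  The effect arm uses a 20,000-individual exposure
  cohort and h² = 0.8 so the known weak-instrument attenuation factor
  h²/(h² + m/n_exposure) ≈ 0.982 keeps the bias of α̂ against the
  truth-scale coefficient α/√h² inside the 5% budget and the 95% CI
  coverage near nominal.  With weaker instruments the same attenuation is
  a real (and expected) bias of the method, not of the implementation.
* Clumping oracle: 200 random ≤ 20-SNP instances against a brute-force
  execution of the greedy definition.
* Permutation calibration: 200 exchangeable-null replicates at 200
  permutations each, for both statistics.
* End-to-end recovery: 50 replicates at the full study scale; the target
  must be ranked first, survive Bonferroni over 14 cell types × 3
  thresholds, beat its set-size-matched permutation null
  (p_empirical < 0.05), and replicate (same sign, both split halves
  nominally significant) jointly in ≥ 80% of runs.

## Known limitations

* The leave-set-out z_diff is systematically positive in the planted
  simulation: the complement score is more weak-instrument-diluted than
  the full score, and the removed set carries ≈ 28% of the exposure-score
  variance, so removal genuinely attenuates.  The pipeline therefore
  reports, and the tests assert, that the complement *remains significant*;
  "no significant attenuation" is a property of designs where the removed
  set is a small share of the score.
* α̂ is reported in outcome-SD per unit of weighted dose; absolute values
  depend on the exposure GWAS's effect scale.  Ranking, permutation and
  replication logic use only |α̂| and z, which are standardization-robust.
* The hypergeometric marker test treats mean expression as pseudo-counts;
  with very small `count_scale` the test is conservative.
* No PLINK binary formats, no genome-build liftover, no eQTL/chromatin
  SNP-to-gene linking, no LD-score or genetic-covariance methods.
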