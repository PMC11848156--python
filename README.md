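# cellprs

Cell-type-partitioned polygenic risk score (PRS) association from paired
GWAS summary statistics.

Many complex-trait links — for instance between Alzheimer's disease (AD)
genetic risk and white matter hyperintensity volume (WMHV) on MRI — are
polygenic and biologically opaque.  One way to add cell-level resolution is
to partition an exposure PRS by cell type: restrict the score to SNPs
proximal to genes over-expressed in each brain or cerebrovascular cell type
(smooth muscle cells, pericytes, endothelial cells, …) and ask which
partition carries the association with the outcome.  `cellprs` implements
that analysis end to end for users who have only summary statistics:

* **QC and clumping** — MAF/INFO filtering, greedy p-value-ordered LD
  clumping against a reference panel (±10 Mb, r² ≤ 0.001 by default), and
  exclusion of the *APOE* (chr19:44.5–46 Mb) and MHC (chr6:26–34 Mb)
  regions, with a sensitivity mode that re-includes *APOE*.
* **Gene and cell-type partitioning** — strand-aware SNP→gene windows
  (2 kb upstream / 0.5 kb downstream), one SNP per gene, marker-gene sets
  read from GMT or derived from a mean-expression table by log-fold-change
  plus an upper-tail cumulative hypergeometric test with
  Benjamini–Hochberg FDR control.
* **The gtx/IVW estimator** — for harmonized per-SNP exposure weights *w*
  and outcome statistics *(b, s)*,

      α̂  = Σ(w·b/s²) / Σ(w²/s²),      se(α̂) = (Σ w²/s²)^(−1/2),
      χ²  = (α̂/se)²,                   pseudo-R² = 1 − exp(−χ²/n),

  the inverse-variance-weighted regression of outcome betas on exposure
  weights with no intercept — exact for uncorrelated SNPs and equivalent
  to two-sample Mendelian-randomization IVW, but with no instrument
  inclusion threshold (weak and pleiotropic variants stay in the score).
* **Inference** — Bonferroni/Holm family-wise error control over the
  (cell type × p-threshold) family, a set-size- and threshold-matched
  permutation null (1000 random SNP sets by default), a leave-set-out
  attenuation test using the nested-IVW variance identity
  var(α̂_full − α̂_complement) = se²_complement − se²_full, split-sample
  discovery/replication with fixed-effect meta-analysis, and Spearman rank
  concordance (exact permutation p for ≤ 8 sets).
* **Synthetic studies** — a generator that emulates the whole design
  (gene-anchored SNPs with block LD, 14 cell types, an exposure cohort,
  split outcome cohorts, an LD reference panel, planted low-MAF/low-INFO/
  region/intergenic/multi-gene decoys) with a proportional exposure→outcome
  effect whose causal mass is concentrated in one designated cell type, so
  every stage can be validated against ground truth.

## Worked example

Simulate a study with a smooth-muscle-cell (SMC) signal and analyse it:

```bash
cellprs simulate --seed 7 --n-snps 600 --n-exposure 4000 \
    --n-outcome 4000 --n-ref 1200 --out-dir study/
cellprs pipeline --study-dir study/ --seed 7 --out-dir run/
```

or in Python:

```python
import cellprs as cp

study = cp.simulate_study(cp.SimArchitecture(n_snps=600, n_genes=120,
                                             ld_blocks=[(3, 0.9)] * 40,
                                             n_low_maf=10, n_low_info=10,
                                             n_apoe=8, n_mhc=8,
                                             n_multi_gene=8, n_intergenic=16),
                          n_exposure=4000, n_outcome=4000, n_ref=1200, seed=7)
res = cp.run_pipeline(study.exposure, study.outcome_combined, study.ld_ref,
                      study.genes, study.cell_sets,
                      cp.RunConfig(rng_seed=7, n_perm=200),
                      outcome_discovery=study.outcome_discovery,
                      outcome_replication=study.outcome_replication)
print(res.cell_ranking().head(3))
print(res.whole_genome_scan[["threshold", "m_snps", "alpha", "z", "p"]])
```

which prints

```
set
SMC          10.408131
OPC           3.298554
Microglia     3.073083
Name: z, dtype: float64
   threshold  m_snps     alpha          z             p
0       0.01      29  0.400799  11.969327  5.144398e-33
1       0.50      87  0.347939  11.365154  6.235474e-30
2       1.00     106  0.346270  11.325822  9.775797e-30
```

The ranking lists cell types by the absolute standardized association of
their partitioned score with the outcome: the planted SMC set leads by a
wide margin (z ≈ 10.4 against ≈ 3.3 for the best decoy), and the
whole-genome score recovers a positive α̂ at every p-threshold.
`res.cell_scan_fwe` carries the FWE-adjusted p-values, `res.permutation`
the set-size-matched null location, `res.leave_out` the attenuation test,
and `res.replication["meta"]` the discovery/replication consistency flags.

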