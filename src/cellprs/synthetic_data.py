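"""A complete synthetic study with a planted cell-type signal.

The generator emulates the ingredients of a cell-type-partitioned
risk-score analysis: a genome of gene-anchored SNPs with block LD, marker
gene sets for 14 brain/vascular cell types, an exposure cohort providing
per-SNP weights via its own GWAS, independent outcome cohorts (with a
discovery/replication split) whose trait depends on the exposure genetic
score through a single proportional effect ``alpha_true``, and an external
reference panel for LD.  Causal effect mass is concentrated in genes
belonging to one designated target cell type, so every downstream stage of
the pipeline has ground truth to recover.

Planted decoys exercise the QC path: low-MAF and low-INFO variants, SNPs
inside the APOE and MHC exclusion regions (the APOE ones carry large
effects, mimicking the locus the published filters guard against),
intergenic SNPs that map to no gene, and SNPs proximal to two genes.

LD model: within a block, every non-seed gamete copies the block seed's
allele with probability r and draws fresh otherwise, so the configured r
is the seed–member allele correlation (and approximately the dosage
correlation).  Blocks share a single MAF; SNPs in distinct blocks are
independent.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._rng import substream
from .errors import ConfigError, DataError
from .sumstats_io import (CellTypeSets, DosageTable, GeneRecord, SummaryStats,
                          write_dosage_matrix, write_gene_annotation, write_gene_sets,
                          write_sumstats)

logger = logging.getLogger("cellprs")

#: brain and cerebrovascular cell types, smooth muscle cells first
DEFAULT_CELL_TYPES = [
    "SMC", "Pericyte", "Endothelial", "Ependymal", "Astrocyte", "Microglia",
    "Oligodendrocyte", "OPC", "ExcitatoryNeuron", "InhibitoryNeuron",
    "Fibroblast", "PerivascularMacrophage", "Tcell", "ChoroidPlexus",
]

_AUTOSOMES = ["1", "2", "3", "4"]
_GENE_SPACING = 2_000_000
_GENE_LENGTH = 10_000


@dataclass
class SimArchitecture:
    """Structural parameters of the synthetic study."""

    n_snps: int = 3000
    n_genes: int = 600
    cell_types: list = field(default_factory=lambda: list(DEFAULT_CELL_TYPES))
    target_cell_type: str = "SMC"
    alpha_true: float = 0.3
    h2_exposure: float = 0.5
    maf_range: tuple = (0.05, 0.5)
    frac_causal: float = 0.2
    enrichment: float = 5.0
    n_low_maf: int = 30
    n_low_info: int = 30
    n_apoe: int = 20
    n_mhc: int = 20
    n_multi_gene: int = 30
    n_intergenic: int = 60
    ld_blocks: list = field(default_factory=lambda: [(3, 0.9)] * 200)
    apoe_effect_scale: float = 5.0
    noncoding_every: int = 20   # every k-th gene is non-protein-coding

    def __post_init__(self) -> None:
        if self.target_cell_type not in self.cell_types:
            raise ConfigError(f"target {self.target_cell_type!r} not among cell types")
        if not 0 <= self.frac_causal <= 1:
            raise ConfigError("frac_causal must lie in [0, 1]")
        if not 0 <= self.h2_exposure < 1:
            raise ConfigError("h2_exposure must lie in [0, 1)")
        for name in ("n_low_maf", "n_low_info", "n_apoe", "n_mhc", "n_multi_gene", "n_intergenic"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for size, r in self.ld_blocks:
            if size > self.n_snps:
                raise ConfigError(f"LD block of size {size} exceeds n_snps={self.n_snps}")
            if not 0 <= r <= 1:
                raise ConfigError("within-block r must lie in [0, 1]")
        n_special = (self.n_apoe + self.n_mhc + self.n_multi_gene + self.n_intergenic)
        if n_special + self.n_low_maf + self.n_low_info >= self.n_snps:
            raise ConfigError("decoy counts exceed n_snps")


@dataclass
class SimTruth:
    """Ground truth recorded before any noise is added; treat as immutable.

    ``df`` has one row per SNP, aligned with the variant table / dosage
    rows: snp_id, chrom, pos, gene, cell_type, causal, beta_std (effect on
    the standardised-genotype scale), w_dose (per-dose effect).
    """

    df: pd.DataFrame
    alpha_true: float
    h2_exposure: float
    target_cell_type: str
    enrichment: float

    @property
    def causal_snps(self) -> list:
        return list(self.df.loc[self.df["causal"], "snp_id"])

    def mean_sq_effect(self, cell_type: Optional[str]) -> float:
        """Mean squared standardized causal effect in (or outside) a cell type."""
        d = self.df[self.df["causal"]]
        if cell_type is None:
            d = d[d["cell_type"] != self.target_cell_type]
        else:
            d = d[d["cell_type"] == cell_type]
        return float((d["beta_std"] ** 2).mean()) if len(d) else 0.0


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def generate_gene_annotation(arch: SimArchitecture, rng: np.random.Generator) -> list[GeneRecord]:
    """Lay out genes on four autosomes, 2 Mb apart, 10 kb long.

    A deterministic subset of adjacent gene pairs is squeezed to a 1 kb gap
    (both on the + strand) so that their proximity windows overlap — these
    host the planted multi-gene SNPs.
    """
    per_chrom = arch.n_genes // len(_AUTOSOMES)
    extra = arch.n_genes - per_chrom * len(_AUTOSOMES)
    n_pairs = (arch.n_multi_gene + 1) // 2
    squeeze: set[tuple[str, int]] = set()
    pairs_on_chrom = {c: 0 for c in _AUTOSOMES}
    for p in range(n_pairs):
        chrom = _AUTOSOMES[p % len(_AUTOSOMES)]
        host = 1 + 3 * pairs_on_chrom[chrom]
        pairs_on_chrom[chrom] += 1
        if host + 1 >= per_chrom:
            raise ConfigError("too many multi-gene pairs for this gene grid")
        squeeze.add((chrom, host + 1))  # gene following the host is squeezed

    genes: list[GeneRecord] = []
    gid = 0
    for ci, chrom in enumerate(_AUTOSOMES):
        n_here = per_chrom + (1 if ci < extra else 0)
        prev_end = None
        for k in range(n_here):
            start = _GENE_SPACING * (k + 1)
            if (chrom, k) in squeeze and prev_end is not None:
                start = prev_end + 1001
            end = start + _GENE_LENGTH - 1
            strand = "+" if ((chrom, k) in squeeze or (chrom, k + 1) in squeeze
                             or rng.random() < 0.5) else "-"
            coding = (gid % arch.noncoding_every) != arch.noncoding_every - 1
            genes.append(GeneRecord(gene_id=f"G{gid:04d}", chrom=chrom, start=start,
                                    end=end, strand=strand, protein_coding=coding))
            prev_end = end
            gid += 1
    return genes


def generate_cell_type_sets(arch: SimArchitecture, genes,
                            rng: np.random.Generator) -> CellTypeSets:
    """Partition all genes evenly and randomly among the cell types."""
    ids = [g.gene_id for g in genes]
    perm = rng.permutation(len(ids))
    groups = np.array_split(perm, len(arch.cell_types))
    return CellTypeSets({cell: {ids[i] for i in grp}
                         for cell, grp in zip(arch.cell_types, groups)})


def generate_expression(genes, sets: CellTypeSets, rng: np.random.Generator,
                        base: float = 5.0, fold: float = 8.0,
                        noise_sd: float = 0.25) -> tuple[pd.DataFrame, pd.Series]:
    """Mean-expression table consistent with the marker sets.

    Marker genes are expressed ``fold`` times above base in their own cell
    type; log-normal multiplicative noise everywhere.  Returns the table
    and the per-gene background mean (row mean across cell types).
    """
    ids = [g.gene_id for g in genes]
    cells = sets.names
    gene_cell = {g: c for c in cells for g in sets[c]}
    noise = rng.normal(0.0, noise_sd, size=(len(ids), len(cells)))
    expr = base * np.exp2(noise)
    for i, g in enumerate(ids):
        c = gene_cell.get(g)
        if c is not None:
            expr[i, cells.index(c)] *= fold
    table = pd.DataFrame(expr, index=pd.Index(ids, name="gene_id"), columns=cells)
    return table, table.mean(axis=1)


def plan_variants(arch: SimArchitecture, genes, rng: np.random.Generator) -> pd.DataFrame:
    """Place every SNP: genic SNPs inside gene bodies, decoys as planted.

    Returns the variant table sorted by (chromosome, position) with columns
    SNP, CHR, BP, A1, A2, maf, INFO, role, gene_planted, block_id, block_r,
    block_seed.  Low-MAF and low-INFO decoys are genic (they fail QC, not
    mapping); APOE/MHC decoys sit inside the exclusion regions; intergenic
    decoys sit far from every gene window; multi-gene decoys sit where two
    squeezed genes' windows overlap.
    """
    coding = [g for g in genes if g.protein_coding]
    rows = []

    # multi-gene decoys in squeezed-pair overlap zones
    pairs = []
    for a, b in zip(genes, genes[1:]):
        if a.chrom == b.chrom and b.start - a.end == 1001 and a.strand == b.strand == "+":
            pairs.append((a, b))
    if arch.n_multi_gene and not pairs:
        raise ConfigError("no squeezed gene pairs available for multi-gene decoys")
    for i in range(arch.n_multi_gene):
        a, b = pairs[i % len(pairs)]
        pos = a.end - 100 - 37 * (i // len(pairs))
        rows.append(dict(CHR=a.chrom, BP=pos, role="multi", gene=a.gene_id))

    for i in range(arch.n_intergenic):
        rows.append(dict(CHR=_AUTOSOMES[i % len(_AUTOSOMES)],
                         BP=100_000 + 20_000 * (i // len(_AUTOSOMES)),
                         role="intergenic", gene=""))
    for i in range(arch.n_apoe):
        rows.append(dict(CHR="19", BP=44_600_000 + 60_000 * i, role="apoe", gene=""))
    for i in range(arch.n_mhc):
        rows.append(dict(CHR="6", BP=26_500_000 + 300_000 * i, role="mhc", gene=""))

    # genic SNPs (including the low-MAF / low-INFO decoys) round-robin over genes
    n_genic = arch.n_snps - len(rows)
    all_genes = list(genes)
    counts = np.zeros(len(all_genes), dtype=int)
    for i in range(n_genic):
        counts[i % len(all_genes)] += 1
    genic_roles = (["low_maf"] * arch.n_low_maf + ["low_info"] * arch.n_low_info
                   + ["genic"] * (n_genic - arch.n_low_maf - arch.n_low_info))
    genic_roles = list(rng.permutation(genic_roles))
    gi = 0
    gene_rows: list[list[int]] = []
    for g, c in zip(all_genes, counts):
        if c == 0:
            gene_rows.append([])
            continue
        # offsets stay below 9000 so genic SNPs never collide with the
        # multi-gene decoys planted near the gene tail
        offsets = rng.choice(9000, size=c, replace=False)
        idxs = []
        for off in sorted(offsets):
            rows.append(dict(CHR=g.chrom, BP=g.start + int(off),
                             role=genic_roles[gi], gene=g.gene_id))
            idxs.append(len(rows) - 1)
            gi += 1
        gene_rows.append(idxs)

    df = pd.DataFrame(rows)

    # LD blocks: consume the block list over genes with enough genic SNPs
    df["block_id"] = -1
    df["block_r"] = 0.0
    df["block_seed"] = False
    block_iter = iter(enumerate(arch.ld_blocks))
    nxt = next(block_iter, None)
    for idxs in gene_rows:
        if nxt is None:
            break
        bid, (size, r) = nxt
        if len(idxs) >= size:
            members = idxs[:size]
            df.loc[members, "block_id"] = bid
            df.loc[members, "block_r"] = r
            df.loc[members[0], "block_seed"] = True
            nxt = next(block_iter, None)

    # frequencies, imputation quality, alleles
    lo, hi = arch.maf_range
    maf = rng.uniform(lo, hi, size=len(df))
    maf[df["role"] == "low_maf"] = rng.uniform(0.001, 0.009, size=int((df["role"] == "low_maf").sum()))
    for bid, grp in df[df["block_id"] >= 0].groupby("block_id"):
        maf[grp.index] = maf[grp.index[0]]
    info = rng.uniform(0.92, 1.0, size=len(df))
    info[df["role"] == "low_info"] = rng.uniform(0.5, 0.89, size=int((df["role"] == "low_info").sum()))
    alleles = np.array(list("ACGT"))
    a1 = rng.integers(0, 4, size=len(df))
    a2 = (a1 + rng.integers(1, 4, size=len(df))) % 4
    df["maf"] = maf
    df["INFO"] = info
    df["A1"] = alleles[a1]
    df["A2"] = alleles[a2]
    df = df.rename(columns={"gene": "gene_planted"})

    from .sumstats_io import chrom_sort_key
    df["_k"] = df["CHR"].map(chrom_sort_key)
    df = df.sort_values(["_k", "BP"], kind="stable").drop(columns="_k").reset_index(drop=True)
    if df.duplicated(subset=["CHR", "BP"]).any():
        raise ConfigError("variant layout produced duplicate positions")
    df.insert(0, "SNP", [f"rs{100000 + i}" for i in range(len(df))])
    return df


# ---------------------------------------------------------------------------
# genotypes, effects, phenotypes, GWAS
# ---------------------------------------------------------------------------

def simulate_genotypes(arch: SimArchitecture, n_ind: int, rng: np.random.Generator,
                       variants: Optional[pd.DataFrame] = None,
                       genes=None) -> tuple[np.ndarray, pd.DataFrame]:
    """Hardy-Weinberg dosages with haplotype-copy LD blocks.

    Returns (dosages, variants): dosages is float32 with shape
    (n_snps, n_ind); rows align with the variant table.
    """
    if n_ind < 50:
        raise ConfigError("n_ind must be >= 50")
    if variants is None:
        if genes is None:
            genes = generate_gene_annotation(arch, rng)
        variants = plan_variants(arch, genes, rng)
    p = variants["maf"].to_numpy(float)[:, None]

    blocks = []
    for bid, grp in variants[variants["block_id"] >= 0].groupby("block_id"):
        seed_rows = grp.index[grp["block_seed"]]
        seed_row = int(seed_rows[0]) if len(seed_rows) else int(grp.index[0])
        members = [int(i) for i in grp.index if i != seed_row]
        blocks.append((seed_row, members, float(grp["block_r"].iloc[0])))

    dose = np.zeros((len(variants), n_ind), dtype=np.float32)
    for _gamete in range(2):
        allele = (rng.random((len(variants), n_ind), dtype=np.float32) < p)
        for seed_row, members, r in blocks:
            for m in members:
                copy = rng.random(n_ind, dtype=np.float32) < r
                allele[m, copy] = allele[seed_row, copy]
        dose += allele.astype(np.float32)
    return dose, variants


def build_architecture(arch: SimArchitecture, genes, sets: CellTypeSets,
                       rng: np.random.Generator,
                       variants: pd.DataFrame) -> SimTruth:
    """Draw true exposure effects with mass concentrated in the target cell type.

    Causal SNPs are a ``frac_causal`` sample of the genic SNPs; their
    standardized effects are N(0, enrichment) for SNPs in target-cell-type
    genes and N(0, 1) elsewhere.  APOE-region decoys are always causal with
    N(0, apoe_effect_scale²) effects; MHC decoys are never causal.
    """
    gene_ids = {g.gene_id for g in genes}
    covered = sets.all_genes()
    if not gene_ids <= covered:
        raise ConfigError(f"cell-type sets do not cover all genes "
                          f"({len(gene_ids - covered)} uncovered)")
    gene_cell = {}
    for cell in sets:
        for g in sets[cell]:
            gene_cell.setdefault(g, cell)

    df = variants[["SNP", "CHR", "BP", "gene_planted", "role", "maf"]].copy()
    df = df.rename(columns={"SNP": "snp_id", "CHR": "chrom", "BP": "pos",
                            "gene_planted": "gene"})
    df["cell_type"] = df["gene"].map(lambda g: gene_cell.get(g, ""))

    genic = df.index[df["role"].isin(["genic", "low_maf", "low_info", "multi"])]
    n_causal = int(round(arch.frac_causal * len(genic)))
    causal_idx = rng.choice(genic, size=n_causal, replace=False) if n_causal else np.array([], int)
    causal = np.zeros(len(df), dtype=bool)
    causal[causal_idx] = True
    causal[df["role"] == "apoe"] = True

    beta_std = np.zeros(len(df))
    is_target = (df["cell_type"] == arch.target_cell_type).to_numpy()
    draw = rng.normal(size=len(df))
    scale = np.where(is_target, np.sqrt(arch.enrichment), 1.0)
    scale = np.where(df["role"] == "apoe", arch.apoe_effect_scale, scale)
    beta_std[causal] = (draw * scale)[causal]
    sd_geno = np.sqrt(2 * df["maf"] * (1 - df["maf"])).to_numpy()
    df["causal"] = causal
    df["beta_std"] = beta_std
    df["w_dose"] = np.where(sd_geno > 0, beta_std / sd_geno, 0.0)
    return SimTruth(df=df.drop(columns=["role", "maf"]), alpha_true=arch.alpha_true,
                    h2_exposure=arch.h2_exposure,
                    target_cell_type=arch.target_cell_type, enrichment=arch.enrichment)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_phenotypes(truth: SimTruth, dosages: np.ndarray, rng: np.random.Generator,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exposure liability and outcome phenotype for one cohort.

    The genetic score G = Σ w_dose·dose is standardized; the exposure
    liability mixes G with environmental noise at heritability
    ``h2_exposure``; the outcome is alpha_true·G plus residual noise scaled
    so its variance is one.  Returns (exposure, outcome, G), each
    standardized.
    """
    h2 = truth.h2_exposure
    a = truth.alpha_true
    if not 0 <= h2 < 1:
        raise ConfigError("h2_exposure must lie in [0, 1)")
    if abs(a) > 1:
        raise ConfigError("alpha_true must lie in [-1, 1]")
    w = truth.df["w_dose"].to_numpy(float)
    if dosages.shape[0] != len(w):
        raise DataError("dosage rows do not match truth table")
    g_raw = w @ np.asarray(dosages, dtype=float)
    g = _standardize(g_raw)
    n = g.size
    exposure = _standardize(np.sqrt(h2) * g + np.sqrt(1 - h2) * rng.normal(size=n))
    resid_sd = np.sqrt(max(0.0, 1 - a * a))
    y = a * g + resid_sd * rng.normal(size=n)
    outcome = _standardize(y) if y.std() > 0 else y
    return exposure, outcome, g


def run_gwas(dosages: np.ndarray, phenotype: np.ndarray, variants: pd.DataFrame,
             trait: str = "trait", chunk: int = 512) -> SummaryStats:
    """Marginal per-SNP linear regression with intercept, vectorized.

    beta = cov(dose, y)/var(dose); SE from the residual variance with n−2
    degrees of freedom; p from the t statistic; MAF from the empirical
    coded-allele frequency; INFO carried over as planted metadata.
    Monomorphic SNPs are dropped with a log entry.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if n <= 2:
        raise DataError("GWAS needs more than two individuals")
    yc = y - y.mean()
    syy = float(yc @ yc)

    m = dosages.shape[0]
    beta = np.empty(m)
    ss_x = np.empty(m)
    freq = np.empty(m)
    for lo in range(0, m, chunk):
        X = np.asarray(dosages[lo:lo + chunk], dtype=float)
        mx = X.mean(axis=1)
        sxy = X @ yc
        sxx = np.einsum("ij,ij->i", X, X) - n * mx * mx
        with np.errstate(invalid="ignore", divide="ignore"):
            beta[lo:lo + chunk] = np.where(sxx > 0, sxy / sxx, np.nan)
        ss_x[lo:lo + chunk] = sxx
        freq[lo:lo + chunk] = mx / 2.0

    mono = ~(ss_x > 1e-12)
    if mono.any():
        logger.info("run_gwas: dropped %d monomorphic SNP(s)", int(mono.sum()))
    sse = np.maximum(syy - beta * beta * ss_x, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sse / (n - 2) / ss_x)
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pval = np.maximum(2.0 * sps.t.sf(np.abs(tstat), df=n - 2), 1e-300)
    maf = np.minimum(freq, 1 - freq)

    keep = ~mono & (maf > 0)
    df = pd.DataFrame({
        "SNP": variants["SNP"].to_numpy(), "CHR": variants["CHR"].to_numpy(),
        "BP": variants["BP"].to_numpy(), "A1": variants["A1"].to_numpy(),
        "A2": variants["A2"].to_numpy(), "BETA": beta, "SE": se, "P": pval,
        "MAF": maf, "INFO": variants["INFO"].to_numpy(), "N": n,
    })[keep].reset_index(drop=True)
    return SummaryStats(trait=trait, n_total=n, table=df)


def split_sample(dosages: np.ndarray, phenotype: np.ndarray, frac_discovery: float,
                 rng: np.random.Generator, variants: pd.DataFrame,
                 trait: str = "trait") -> dict:
    """Random discovery/replication split plus the combined GWAS.

    Returns a dict with SummaryStats under keys ``discovery``,
    ``replication``, ``combined`` and the index arrays used.
    """
    if not 0 < frac_discovery < 1:
        raise ConfigError("frac_discovery must lie in (0, 1)")
    n = len(phenotype)
    n_disc = int(round(frac_discovery * n))
    if min(n_disc, n - n_disc) < 50:
        raise ConfigError("split leaves fewer than 50 individuals in one half")
    perm = rng.permutation(n)
    idx_d, idx_r = np.sort(perm[:n_disc]), np.sort(perm[n_disc:])
    out = {
        "discovery": run_gwas(dosages[:, idx_d], phenotype[idx_d], variants,
                              trait=f"{trait}_discovery"),
        "replication": run_gwas(dosages[:, idx_r], phenotype[idx_r], variants,
                                trait=f"{trait}_replication"),
        "combined": run_gwas(dosages, phenotype, variants, trait=f"{trait}_combined"),
        "idx_discovery": idx_d, "idx_replication": idx_r,
    }
    return out


# ---------------------------------------------------------------------------
# whole-study orchestration
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """Everything one synthetic study produces."""

    arch: SimArchitecture
    genes: list
    cell_sets: CellTypeSets
    expression: pd.DataFrame
    background: pd.Series
    variants: pd.DataFrame
    truth: SimTruth
    exposure: SummaryStats
    outcome_combined: SummaryStats
    outcome_discovery: SummaryStats
    outcome_replication: SummaryStats
    ld_ref: DosageTable
    n_exposure: int
    n_outcome: int
    n_discovery: int
    n_replication: int
    outcome_dosages: Optional[np.ndarray] = None
    outcome_phenotype: Optional[np.ndarray] = None
    outcome_score: Optional[np.ndarray] = None


def simulate_study(arch: Optional[SimArchitecture] = None, n_exposure: int = 20_000,
                   n_outcome: int = 20_000, n_ref: int = 2504,
                   frac_discovery: float = 2 / 3, seed: int = 0,
                   keep_individual: bool = False) -> StudyData:
    """Generate the full two-sample study from one seed.

    The exposure GWAS comes from its own cohort (no overlap with the
    outcome cohorts, mirroring a two-sample design); the outcome cohort is
    split into discovery and replication; an independent reference panel
    provides LD.  All randomness flows through named substreams of ``seed``.
    """
    arch = arch or SimArchitecture()
    rng_layout = substream(seed, "layout")
    genes = generate_gene_annotation(arch, rng_layout)
    cell_sets = generate_cell_type_sets(arch, genes, rng_layout)
    expression, background = generate_expression(genes, cell_sets,
                                                 substream(seed, "expression"))
    variants = plan_variants(arch, genes, rng_layout)
    truth = build_architecture(arch, genes, cell_sets, substream(seed, "effects"), variants)

    dos_exp, _ = simulate_genotypes(arch, n_exposure, substream(seed, "genotypes_exposure"),
                                    variants=variants)
    liab, _, _ = simulate_phenotypes(truth, dos_exp, substream(seed, "phenotypes_exposure"))
    exposure = run_gwas(dos_exp, liab, variants, trait="AD_exposure")
    del dos_exp

    dos_out, _ = simulate_genotypes(arch, n_outcome, substream(seed, "genotypes_outcome"),
                                    variants=variants)
    _, y, g = simulate_phenotypes(truth, dos_out, substream(seed, "phenotypes_outcome"))
    split = split_sample(dos_out, y, frac_discovery, substream(seed, "split"),
                         variants, trait="WMHV")

    dos_ref, _ = simulate_genotypes(arch, n_ref, substream(seed, "genotypes_reference"),
                                    variants=variants)
    ld_ref = DosageTable(
        pd.DataFrame(dos_ref.astype(float), index=pd.Index(variants["SNP"], name="SNP"),
                     columns=[f"R{i:04d}" for i in range(n_ref)]),
        pd.Series(variants["A1"].to_numpy(), index=variants["SNP"].to_numpy()),
    )
    del dos_ref

    n_disc = len(split["idx_discovery"])
    return StudyData(
        arch=arch, genes=genes, cell_sets=cell_sets, expression=expression,
        background=background, variants=variants, truth=truth, exposure=exposure,
        outcome_combined=split["combined"], outcome_discovery=split["discovery"],
        outcome_replication=split["replication"], ld_ref=ld_ref,
        n_exposure=n_exposure, n_outcome=n_outcome, n_discovery=n_disc,
        n_replication=n_outcome - n_disc,
        outcome_dosages=dos_out if keep_individual else None,
        outcome_phenotype=y if keep_individual else None,
        outcome_score=g if keep_individual else None,
    )


def write_study(study: StudyData, out_dir) -> dict:
    """Write every study artefact to ``out_dir``; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": out / "exposure.tsv",
        "outcome_combined": out / "outcome_combined.tsv",
        "outcome_discovery": out / "outcome_discovery.tsv",
        "outcome_replication": out / "outcome_replication.tsv",
        "genes": out / "genes.bed",
        "cell_sets": out / "cell_sets.gmt",
        "expression": out / "expression.tsv",
        "ld_ref": out / "ld_ref.tsv",
        "truth": out / "truth.json",
    }
    write_sumstats(study.exposure, paths["exposure"])
    write_sumstats(study.outcome_combined, paths["outcome_combined"])
    write_sumstats(study.outcome_discovery, paths["outcome_discovery"])
    write_sumstats(study.outcome_replication, paths["outcome_replication"])
    write_gene_annotation(study.genes, paths["genes"])
    write_gene_sets({c: study.cell_sets[c] for c in study.cell_sets}, paths["cell_sets"])
    expr = study.expression.copy()
    expr["background"] = study.background
    expr.to_csv(paths["expression"], sep="\t")
    write_dosage_matrix(study.ld_ref, paths["ld_ref"])
    truth = {
        "alpha_true": study.truth.alpha_true,
        "h2_exposure": study.truth.h2_exposure,
        "target_cell_type": study.truth.target_cell_type,
        "enrichment": study.truth.enrichment,
        "n_discovery": study.n_discovery,
        "n_replication": study.n_replication,
        "per_snp": study.truth.df.to_dict(orient="list"),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh)
    return paths
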