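"""Variant QC, fixed-region exclusion, and greedy LD clumping.

QC keeps variants with MAF and INFO at or above their thresholds (exclusion
is strict ``<``, matching the published filter).  Region exclusion removes
variants inside closed intervals — by default the APOE locus
(chr19:44,500,000–46,000,000) and the MHC (chr6:26,000,000–34,000,000).
Clumping greedily picks index SNPs in order of exposure p-value and removes
every same-chromosome SNP within the window whose squared dosage correlation
with the index exceeds ``r2_max``, leaving the approximately independent SNP
pool all scores are built from.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .sumstats_io import DosageTable, SummaryStats, chrom_sort_key, normalize_chrom

logger = logging.getLogger("cellprs")


@dataclass(frozen=True)
class Region:
    """A closed genomic interval [start_bp, end_bp] on one chromosome."""

    chrom: str
    start_bp: int
    end_bp: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ConfigError(f"region {self.label}: start > end")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    @classmethod
    def from_tuple(cls, t) -> "Region":
        chrom, start, end, *label = t
        return cls(str(chrom), int(start), int(end), label[0] if label else "")


APOE_REGION = Region("19", 44_500_000, 46_000_000, "APOE")
MHC_REGION = Region("6", 26_000_000, 34_000_000, "MHC")
DEFAULT_EXCLUDED_REGIONS = [APOE_REGION, MHC_REGION]


@dataclass
class ClumpResult:
    """Outcome of greedy clumping.

    ``retained`` lists index SNPs in processing order; ``removed`` maps each
    absorbed SNP to the index SNP that removed it.  Every input SNP appears
    exactly once across the two.
    """

    retained: list
    removed: dict
    window_kb: int
    r2_max: float
    missing_from_reference: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, "index", "") for s in self.retained]
        rows += [(s, "removed", idx) for s, idx in self.removed.items()]
        return pd.DataFrame(rows, columns=["snp_id", "status", "index_snp"])


def filter_variants(stats: SummaryStats, maf_min: float, info_min: float) -> SummaryStats:
    """Retain variants with MAF >= maf_min and INFO >= info_min."""
    if not 0 < maf_min <= 0.5:
        raise ConfigError(f"maf_min out of range: {maf_min}")
    if not 0 < info_min <= 1.2:
        raise ConfigError(f"info_min out of range: {info_min}")
    t = stats.table
    low_maf = t["MAF"] < maf_min
    low_info = t["INFO"] < info_min
    keep = ~(low_maf | low_info)
    logger.info("filter_variants: removed %d low-MAF, %d low-INFO of %d variants",
                int(low_maf.sum()), int((low_info & ~low_maf).sum()), len(t))
    return SummaryStats(stats.trait, stats.n_total, t[keep].reset_index(drop=True))


def exclude_regions(stats: SummaryStats, regions) -> SummaryStats:
    """Remove variants falling inside any region (both boundaries inclusive)."""
    t = stats.table
    drop = pd.Series(False, index=t.index)
    for region in regions:
        if not isinstance(region, Region):
            region = Region.from_tuple(region)
        hit = (t["CHR"] == region.chrom) & (t["BP"] >= region.start_bp) & (t["BP"] <= region.end_bp)
        if hit.any():
            logger.info("exclude_regions: %d variant(s) in %s", int(hit.sum()),
                        region.label or f"{region.chrom}:{region.start_bp}-{region.end_bp}")
        drop |= hit
    return SummaryStats(stats.trait, stats.n_total, t[~drop].reset_index(drop=True))


def compute_r2(snp_a: str, snp_b: str, ld_ref: DosageTable) -> float:
    """Squared Pearson correlation of reference dosages for two SNPs.

    A zero-variance dosage vector yields r² = 0 with a warning (the SNP
    carries no LD information in this reference panel).
    """
    a = ld_ref.dosages(snp_a)
    b = ld_ref.dosages(snp_b)
    a = a - a.mean()
    b = b - b.mean()
    va, vb = float(a @ a), float(b @ b)
    if va == 0.0 or vb == 0.0:
        warnings.warn(f"zero-variance dosages for {snp_a if va == 0 else snp_b}; r2 set to 0")
        return 0.0
    c = float(a @ b)
    return min(1.0, c * c / (va * vb))


def clump(stats: SummaryStats, ld_ref: DosageTable, window_kb: int,
          r2_max: float, missing_policy: str = "retain") -> ClumpResult:
    """Greedy p-value-ordered LD clumping.

    Repeatedly take the unprocessed SNP with the smallest exposure p-value
    (ties broken by smaller (chrom, pos)) as an index SNP, and remove every
    unprocessed same-chromosome SNP within ±``window_kb``×1000 bp whose r²
    with the index exceeds ``r2_max``.  SNPs absent from the LD reference
    are treated as uncorrelated with everything (``missing_policy="retain"``,
    the permissive behaviour) or dropped up front (``"drop"``).
    """
    if window_kb <= 0:
        raise ConfigError("window_kb must be positive")
    if not 0 <= r2_max < 1:
        raise ConfigError("r2_max must lie in [0, 1)")
    if missing_policy not in ("retain", "drop"):
        raise ConfigError(f"unknown missing_policy {missing_policy!r}")

    t = stats.table
    window_bp = window_kb * 1000
    in_ref = t["SNP"].isin(set(map(str, ld_ref.snp_ids))).to_numpy()
    missing = list(t.loc[~in_ref, "SNP"])
    if missing:
        logger.warning("clump: %d SNP(s) absent from LD reference (%s policy)",
                       len(missing), missing_policy)

    work = t[["SNP", "CHR", "BP", "P"]].copy()
    if missing_policy == "drop":
        work = work[in_ref]
    order = work.assign(_k=work["CHR"].map(chrom_sort_key)) \
                .sort_values(["P", "_k", "BP"], kind="stable").index

    # pre-centred reference dosages for fast pairwise r2
    present = work["SNP"][work["SNP"].isin(set(map(str, ld_ref.snp_ids)))]
    if len(present):
        ref = ld_ref.matrix.loc[present].to_numpy(dtype=float)
        ref = ref - ref.mean(axis=1, keepdims=True)
        norms = np.sqrt((ref * ref).sum(axis=1))
        row_of = {s: i for i, s in enumerate(present)}
    else:
        ref, norms, row_of = np.empty((0, 0)), np.empty(0), {}

    chrom_arr = work["CHR"].to_numpy()
    pos_arr = work["BP"].to_numpy()
    snp_arr = work["SNP"].to_numpy()
    # per-chromosome position-sorted views for window queries
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in pd.unique(chrom_arr):
        idx = np.where(chrom_arr == chrom)[0]
        srt = idx[np.argsort(pos_arr[idx], kind="stable")]
        by_chrom[chrom] = (pos_arr[srt], srt)

    removed: dict[str, str] = {}
    removed_mask = np.zeros(len(work), dtype=bool)
    indexed_mask = np.zeros(len(work), dtype=bool)
    retained: list[str] = []
    iloc_of = {lab: i for i, lab in enumerate(work.index)}

    for lab in order:
        i = iloc_of[lab]
        if removed_mask[i]:
            continue
        indexed_mask[i] = True
        retained.append(snp_arr[i])
        if snp_arr[i] not in row_of:
            continue  # uncorrelated with everything by policy
        positions, ilocs = by_chrom[chrom_arr[i]]
        lo = np.searchsorted(positions, pos_arr[i] - window_bp, side="left")
        hi = np.searchsorted(positions, pos_arr[i] + window_bp, side="right")
        cand = ilocs[lo:hi]
        cand = cand[~removed_mask[cand] & ~indexed_mask[cand]]
        if cand.size == 0:
            continue
        ri = row_of[snp_arr[i]]
        have_ref = np.array([snp_arr[j] in row_of for j in cand])
        cand = cand[have_ref]
        if cand.size == 0:
            continue
        rows = np.array([row_of[snp_arr[j]] for j in cand])
        denom = norms[rows] * norms[ri]
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(denom > 0, (ref[rows] @ ref[ri]) ** 2 / denom**2, 0.0)
        hit = cand[r2 > r2_max]
        for j in hit:
            removed[snp_arr[j]] = snp_arr[i]
        removed_mask[hit] = True

    return ClumpResult(retained=retained, removed=removed, window_kb=window_kb,
                       r2_max=r2_max, missing_from_reference=missing)
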