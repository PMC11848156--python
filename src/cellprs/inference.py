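"""Multiplicity control, the set-size-matched permutation null,
leave-set-out attenuation, split-sample replication, and rank concordance.

The permutation null asks whether a cell type's association merely reflects
its SNP-set size: scores are rebuilt from random SNP sets of identical size
drawn from the same p-threshold pool, and the observed |alpha| is located
within that null.  The attenuation test exploits the nested-IVW variance
identity var(alpha_full − alpha_complement) = se_complement² − se_full² to
ask whether removing a cell type's SNPs significantly weakens the
whole-score association.
"""
from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .prs_association import ScoreInstrument, build_instrument, gtx_alpha, gtx_association

logger = logging.getLogger("cellprs")


@dataclass
class PermutationResult:
    """Location of an observed |alpha| within its set-size-matched null."""

    observed_stat: float
    null_mean: float
    null_sd: float
    z_emp: float
    p_two_tailed: float
    p_empirical: float
    n_perm: int
    set_size: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("observed_stat", "null_mean", "null_sd", "z_emp",
                 "p_two_tailed", "p_empirical", "n_perm", "set_size")}


@dataclass
class AttenuationResult:
    """Leave-set-out comparison of the full score vs its complement."""

    alpha_full: float
    se_full: float
    alpha_complement: float
    se_complement: float
    p_complement: float
    z_diff: float
    p_diff: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("alpha_full", "se_full", "alpha_complement", "se_complement",
                 "p_complement", "z_diff", "p_diff")}


def normal_two_tailed_p(z: float) -> float:
    """Two-tailed normal p-value for an empirical z score."""
    return float(2.0 * sps.norm.sf(abs(z)))


def fwe_correct(results: pd.DataFrame, alpha: float = 0.05,
                method: str = "bonferroni") -> pd.DataFrame:
    """Family-wise error control over the tests actually performed.

    ``results`` is a scan table with a ``p`` column; the family size is its
    row count (skipped empty instruments never enter).  Bonferroni is the
    default; Holm's step-down is available.  Returns a copy with ``p_fwe``
    and ``significant`` columns; adjusted p-values never drop below raw ones.
    """
    if results.empty:
        raise DataError("fwe_correct needs a non-empty results table")
    if method not in ("bonferroni", "holm"):
        raise ConfigError(f"unknown FWE method {method!r}")
    out = results.copy()
    p = out["p"].to_numpy(float)
    if method == "bonferroni":
        p_adj = np.minimum(1.0, p * len(p))
    else:
        _, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    out["p_fwe"] = p_adj
    out["significant"] = p_adj < alpha
    out.attrs["n_tests"] = len(p)
    out.attrs["fwe_alpha"] = alpha
    out.attrs["fwe_method"] = method
    return out


def permutation_null(target: ScoreInstrument, pool: pd.DataFrame, n_perm: int,
                     rng: np.random.Generator, n_outcome: Optional[int] = None,
                     statistic: str = "abs_alpha") -> PermutationResult:
    """Set-size-matched permutation null for one cell-type score.

    ``pool`` holds the harmonized pairs already restricted to the target's
    p-threshold (so the null controls for SNP-set size and threshold).
    Each of ``n_perm`` draws takes |target| SNPs uniformly without
    replacement from the pool and refits the score.  Reports both the
    normal-approximation two-tailed p for z_emp and the add-one empirical p.

    ``statistic`` selects the location measure: ``"abs_alpha"`` (the
    absolute score coefficient) or ``"abs_z"`` (the absolute standardised
    association |alpha|/se).  Under a purely proportional outcome model the
    IVW alpha is the same for every valid SNP subset, so |alpha| separates
    a concentrated set from random ones only through weight-noise dilution;
    |alpha|/se additionally credits the concentrated set's precision and is
    the discriminating choice when effects are homogeneous.
    """
    if statistic not in ("abs_alpha", "abs_z"):
        raise ConfigError(f"unknown permutation statistic {statistic!r}")
    k = len(target)
    if k == 0:
        raise DataError("permutation target is empty")
    if len(pool) <= k:
        raise DataError(f"pool ({len(pool)}) must exceed target size ({k})")
    if len(pool) < 2 * k:
        warnings.warn("pool smaller than twice the target set; null may be degenerate")
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")

    def stat(w, b, s):
        alpha, se = gtx_alpha(w, b, s)
        return abs(alpha) if statistic == "abs_alpha" else abs(alpha) / se

    observed = stat(target.snps["w"].to_numpy(float), target.snps["b"].to_numpy(float),
                    target.snps["s"].to_numpy(float))

    w = pool["w"].to_numpy(float)
    b = pool["b"].to_numpy(float)
    s = pool["s"].to_numpy(float)
    num_terms = w * b / (s * s)
    den_terms = w * w / (s * s)
    null = np.empty(n_perm)
    n_pool = len(pool)
    for i in range(n_perm):
        idx = rng.choice(n_pool, size=k, replace=False)
        num = num_terms[idx].sum()
        den = den_terms[idx].sum()
        null[i] = abs(num) / den if statistic == "abs_alpha" else abs(num) / np.sqrt(den)

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0.0:
        raise DataError("degenerate permutation null (zero spread)")
    z_emp = (observed - null_mean) / null_sd
    p_emp = (1.0 + float((null >= observed).sum())) / (n_perm + 1.0)
    return PermutationResult(observed_stat=observed, null_mean=null_mean, null_sd=null_sd,
                             z_emp=float(z_emp), p_two_tailed=normal_two_tailed_p(z_emp),
                             p_empirical=p_emp, n_perm=n_perm, set_size=k)


def leave_set_out(pairs: pd.DataFrame, cell_set, threshold: float,
                  n_outcome: int) -> AttenuationResult:
    """Refit the full score with one cell type's SNPs removed.

    For nested IVW estimates the difference's variance is
    se_complement² − se_full² (the full fit pools the complement's and the
    removed set's precisions), giving z_diff and a two-tailed normal p for
    the attenuation.
    """
    cell_set = set(cell_set)
    full = build_instrument(pairs, threshold, name="full")
    if full.is_empty:
        raise DataError("full instrument is empty")
    comp_ids = set(full.snps["snp_id"]) - cell_set
    if not comp_ids:
        raise DataError("complement instrument is empty (cell set covers all SNPs)")
    comp = build_instrument(pairs, threshold, snp_subset=comp_ids, name="complement")

    fit_f = gtx_association(full, n_outcome)
    fit_c = gtx_association(comp, n_outcome)
    var_diff = fit_c.se_alpha**2 - fit_f.se_alpha**2
    if var_diff < -1e-12:
        raise DataError("nested variance identity violated (se_c^2 < se_f^2)")
    if var_diff <= 0:
        z_diff = 0.0
    else:
        z_diff = (fit_f.alpha_hat - fit_c.alpha_hat) / math.sqrt(var_diff)
    return AttenuationResult(alpha_full=fit_f.alpha_hat, se_full=fit_f.se_alpha,
                             alpha_complement=fit_c.alpha_hat, se_complement=fit_c.se_alpha,
                             p_complement=fit_c.pval, z_diff=float(z_diff),
                             p_diff=normal_two_tailed_p(z_diff))


def fixed_effect_meta(alpha_1: float, se_1: float, alpha_2: float, se_2: float) -> dict:
    """Precision-weighted fixed-effect meta-analysis of two estimates."""
    w1, w2 = se_1**-2, se_2**-2
    alpha = (w1 * alpha_1 + w2 * alpha_2) / (w1 + w2)
    se = (w1 + w2) ** -0.5
    z = alpha / se
    return {"alpha_meta": float(alpha), "se_meta": float(se), "z_meta": float(z),
            "p_meta": normal_two_tailed_p(z)}


def replicate_and_combine(pairs_discovery: pd.DataFrame, pairs_replication: pd.DataFrame,
                          snp_sets: dict, thresholds, n_discovery: int, n_replication: int,
                          pairs_combined: Optional[pd.DataFrame] = None,
                          n_combined: Optional[int] = None,
                          consistency_p: float = 0.05) -> dict:
    """Apply identical instrument definitions to discovery and replication.

    Returns per-sample scan tables, a fixed-effect meta-analysis of the two
    split halves, the combined-sample scan when supplied, and a consistency
    flag per (set, threshold): same sign and both nominal p below
    ``consistency_p``.  Instruments empty in either sample are flagged and
    excluded from the meta table.
    """
    from .prs_association import threshold_scan

    scan_d = threshold_scan(pairs_discovery, thresholds, snp_sets, n_discovery)
    scan_r = threshold_scan(pairs_replication, thresholds, snp_sets, n_replication)
    key = ["set", "threshold"]
    merged = scan_d.table.merge(scan_r.table, on=key, suffixes=("_disc", "_rep"))
    rows = []
    for r in merged.itertuples(index=False):
        meta = fixed_effect_meta(r.alpha_disc, r.se_disc, r.alpha_rep, r.se_rep)
        consistent = (np.sign(r.alpha_disc) == np.sign(r.alpha_rep)
                      and r.p_disc < consistency_p and r.p_rep < consistency_p)
        rows.append({"set": r.set, "threshold": r.threshold, **meta,
                     "consistent": bool(consistent)})
    meta_table = pd.DataFrame(rows, columns=["set", "threshold", "alpha_meta", "se_meta",
                                             "z_meta", "p_meta", "consistent"])
    out = {"discovery": scan_d, "replication": scan_r, "meta": meta_table,
           "skipped": sorted(set(scan_d.skipped) | set(scan_r.skipped))}
    if pairs_combined is not None:
        if n_combined is None:
            n_combined = n_discovery + n_replication
        out["combined"] = threshold_scan(pairs_combined, thresholds, snp_sets, n_combined)
    return out


def _spearman_exact_p(ra: np.ndarray, rb: np.ndarray, rho_obs: float) -> float:
    """Exact two-tailed permutation p for Spearman's rho (n <= 8)."""
    n = len(ra)
    ra_c = ra - ra.mean()
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rb_p = rb[list(perm)]
        rb_c = rb_p - rb_p.mean()
        denom = math.sqrt(float(ra_c @ ra_c) * float(rb_c @ rb_c))
        rho = float(ra_c @ rb_c) / denom
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def rank_concordance(results_a, results_b, value: str = "alpha") -> tuple[float, float]:
    """Spearman rank correlation between two per-set result tables.

    Inputs are mappings / Series keyed by set name, or scan tables (in
    which case ``value`` names the column and one row per set is expected).
    Two-tailed p uses the t approximation, replaced by the exact
    permutation distribution when n <= 8.
    """
    def as_series(x):
        if isinstance(x, pd.DataFrame):
            return x.set_index("set")[value]
        return pd.Series(dict(x)) if not isinstance(x, pd.Series) else x

    a = as_series(results_a)
    b = as_series(results_b)
    shared = a.index.intersection(b.index)
    if len(shared) < 4:
        raise DataError(f"rank concordance needs >= 4 shared keys, got {len(shared)}")
    av = a.loc[shared].to_numpy(float)
    bv = b.loc[shared].to_numpy(float)
    ra = sps.rankdata(av)
    rb = sps.rankdata(bv)
    rho, p_t = sps.spearmanr(av, bv)
    rho = float(rho)
    if len(shared) <= 8:
        return rho, _spearman_exact_p(ra, rb, rho)
    return rho, float(p_t)


def sensitivity_include_region(pairs_with_region: pd.DataFrame, region, threshold: float,
                               n_outcome: int) -> dict:
    """Compare the score fit with vs without one region's SNPs.

    ``pairs_with_region`` must come from a QC run that retained the region.
    Returns both fits and the change in alpha and z.  A region contributing
    no SNPs yields an identity comparison with a warning.
    """
    from .qc_clump import Region

    if not isinstance(region, Region):
        region = Region.from_tuple(region)
    in_region = ((pairs_with_region["chrom"].astype(str) == region.chrom)
                 & (pairs_with_region["pos"] >= region.start_bp)
                 & (pairs_with_region["pos"] <= region.end_bp))
    if not in_region.any():
        warnings.warn(f"region {region.label or region.chrom} contributes no SNPs")
    with_inst = build_instrument(pairs_with_region, threshold, name="with_region")
    without_pairs = pairs_with_region[~in_region]
    without_inst = build_instrument(without_pairs, threshold, name="without_region")
    fit_with = gtx_association(with_inst, n_outcome)
    fit_without = gtx_association(without_inst, n_outcome)
    return {
        "with_region": fit_with, "without_region": fit_without,
        "n_region_snps": int(in_region.sum()),
        "delta_alpha": fit_with.alpha_hat - fit_without.alpha_hat,
        "delta_z": fit_with.z - fit_without.z,
    }
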