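"""The gtx/IVW risk-score association estimator.

Given exposure weights *w* (per-SNP effects on the exposure, per dose of
the coded allele) and outcome statistics *(b, s)* for the same SNPs and
the same coded alleles, the score's effect on the outcome is the
inverse-variance-weighted regression of b on w with no intercept:

    alpha_hat = sum(w b / s^2) / sum(w^2 / s^2)
    se_alpha  = (sum(w^2 / s^2))^(-1/2)
    chi2      = (alpha_hat / se_alpha)^2,  p = upper tail of chi^2_1
    pseudo_R2 = 1 - exp(-chi2 / n)         (likelihood-ratio form)

This is exact when the SNPs are uncorrelated, hence the clumping upstream,
and is equivalent to the IVW estimator of two-sample Mendelian
randomization — with no instrument-strength inclusion criterion, since a
risk-score regression deliberately keeps weak and pleiotropic variants.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError, HarmonizationError
from .sumstats_io import SummaryStats

logger = logging.getLogger("cellprs")

PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass
class ScoreInstrument:
    """A harmonized SNP set defining one risk score at one p-threshold.

    ``snps`` columns: snp_id, chrom, pos, w (exposure beta), p_exp
    (exposure p-value), b (outcome beta), s (outcome SE), palindromic.
    """

    name: str
    p_threshold: float
    snps: pd.DataFrame

    @property
    def is_empty(self) -> bool:
        return len(self.snps) == 0

    def __len__(self) -> int:
        return len(self.snps)


@dataclass
class GtxResult:
    """Estimator output for one instrument."""

    name: str
    p_threshold: float
    alpha_hat: float
    se_alpha: float
    z: float
    pval: float
    chi2: float
    pseudo_r2: float
    m_snps: int
    n_outcome: int

    def to_dict(self) -> dict:
        return {
            "set": self.name, "threshold": self.p_threshold, "m_snps": self.m_snps,
            "alpha": self.alpha_hat, "se": self.se_alpha, "z": self.z,
            "p": self.pval, "pseudo_r2": self.pseudo_r2, "n_outcome": self.n_outcome,
        }


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    pairs = [frozenset(p) for p in zip(a1, a2)]
    targets = tuple(frozenset(p) for p in PALINDROMIC_PAIRS)
    return pd.Series([p in targets for p in pairs], index=a1.index)


def harmonize(exposure: SummaryStats, outcome: SummaryStats,
              palindromic_policy: str = "keep") -> pd.DataFrame:
    """Align outcome betas to the exposure's coded alleles.

    Inner join on SNP id; when the outcome's coded allele is the exposure's
    other allele (and vice versa) the outcome beta is negated; pairs whose
    allele sets differ entirely are dropped with a log entry.  Palindromic
    pairs (A/T, C/G) are kept and flagged by default, or dropped under
    ``palindromic_policy="drop"``.
    """
    if palindromic_policy not in ("keep", "drop"):
        raise ConfigError(f"unknown palindromic_policy {palindromic_policy!r}")
    e = exposure.table[["SNP", "CHR", "BP", "A1", "A2", "BETA", "P"]]
    o = outcome.table[["SNP", "A1", "A2", "BETA", "SE"]]
    m = e.merge(o, on="SNP", suffixes=("_exp", "_out"))
    if m.empty:
        raise HarmonizationError("no shared SNPs between exposure and outcome")

    same = (m["A1_exp"] == m["A1_out"]) & (m["A2_exp"] == m["A2_out"])
    swapped = (m["A1_exp"] == m["A2_out"]) & (m["A2_exp"] == m["A1_out"])
    mismatched = ~(same | swapped)
    if mismatched.any():
        logger.info("harmonize: dropped %d pair(s) with mismatched alleles", int(mismatched.sum()))
    m = m[~mismatched].copy()
    if m.empty:
        raise HarmonizationError("no allele-compatible SNPs between exposure and outcome")

    sign = np.where(m["A1_exp"] == m["A1_out"], 1.0, -1.0)
    pairs = pd.DataFrame({
        "snp_id": m["SNP"].to_numpy(),
        "chrom": m["CHR"].to_numpy(),
        "pos": m["BP"].to_numpy(),
        "w": m["BETA_exp"].to_numpy(float),
        "p_exp": m["P"].to_numpy(float),
        "b": m["BETA_out"].to_numpy(float) * sign,
        "s": m["SE"].to_numpy(float),
        "palindromic": _is_palindromic(m["A1_exp"], m["A2_exp"]).to_numpy(),
    })
    n_pal = int(pairs["palindromic"].sum())
    if n_pal:
        logger.info("harmonize: %d palindromic pair(s) (%s policy)", n_pal, palindromic_policy)
    if palindromic_policy == "drop":
        pairs = pairs[~pairs["palindromic"]].reset_index(drop=True)
        if pairs.empty:
            raise HarmonizationError("all shared SNPs were palindromic and dropped")
    return pairs.reset_index(drop=True)


def build_instrument(pairs: pd.DataFrame, p_threshold: float,
                     snp_subset: Optional[set] = None, name: str = "score") -> ScoreInstrument:
    """Select harmonized pairs with exposure p strictly below the threshold.

    The strict comparison mirrors the published "p < 0.01–1.0" notation; at
    threshold 1.0 a pair with exposure p exactly 1.0 is excluded.  An empty
    selection yields a flagged-empty instrument rather than an error.
    """
    if not 0 < p_threshold <= 1:
        raise ConfigError(f"p_threshold out of range: {p_threshold}")
    keep = pairs["p_exp"] < p_threshold
    if snp_subset is not None:
        keep &= pairs["snp_id"].isin(set(snp_subset))
    sel = pairs[keep].reset_index(drop=True)
    if sel.empty:
        logger.info("instrument %s @ p<%g: empty (flagged)", name, p_threshold)
    return ScoreInstrument(name=name, p_threshold=p_threshold, snps=sel)


def gtx_alpha(w: np.ndarray, b: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Closed-form IVW fit: returns (alpha_hat, se_alpha)."""
    prec = w * w / (s * s)
    denom = float(prec.sum())
    if denom <= 0:
        raise DataError("instrument carries no weight (all w zero?)")
    alpha = float((w * b / (s * s)).sum()) / denom
    return alpha, denom ** -0.5


def gtx_association(inst: ScoreInstrument, n_outcome: int,
                    pseudo_r2_form: str = "lrt") -> GtxResult:
    """Fit the gtx/IVW association for one instrument.

    ``pseudo_r2_form`` selects the likelihood-ratio form 1 − exp(−chi2/n)
    (default) or the first-order variant chi2/n.
    """
    if inst.is_empty:
        raise DataError(f"instrument {inst.name!r} is empty; association impossible")
    if n_outcome <= 2:
        raise DataError("n_outcome must exceed 2")
    if pseudo_r2_form not in ("lrt", "linear"):
        raise ConfigError(f"unknown pseudo_r2_form {pseudo_r2_form!r}")
    w = inst.snps["w"].to_numpy(float)
    b = inst.snps["b"].to_numpy(float)
    s = inst.snps["s"].to_numpy(float)
    if (s <= 0).any():
        raise DataError("all outcome SEs must be strictly positive")
    alpha, se = gtx_alpha(w, b, s)
    z = alpha / se
    chi2 = z * z
    pval = float(sps.chi2.sf(chi2, df=1))
    if pseudo_r2_form == "lrt":
        pseudo = 1.0 - float(np.exp(-chi2 / n_outcome))
    else:
        pseudo = min(1.0, chi2 / n_outcome)
    return GtxResult(name=inst.name, p_threshold=inst.p_threshold, alpha_hat=alpha,
                     se_alpha=se, z=z, pval=pval, chi2=chi2, pseudo_r2=pseudo,
                     m_snps=len(inst), n_outcome=int(n_outcome))


@dataclass
class ScanResult:
    """Results of a (set × threshold) scan plus the skipped empty cells."""

    table: pd.DataFrame
    skipped: list = field(default_factory=list)

    @property
    def n_tests(self) -> int:
        return len(self.table)


def threshold_scan(pairs: pd.DataFrame, thresholds, snp_sets: dict,
                   n_outcome: int, pseudo_r2_form: str = "lrt") -> ScanResult:
    """Fit one gtx association per (set, threshold) combination.

    ``snp_sets`` maps set name → SNP-id subset, or ``None`` for the full
    pool (e.g. the whole-genome score).  Flagged-empty instruments are
    skipped and recorded in ``skipped``.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(set(thresholds)):
        raise ConfigError("thresholds must be strictly increasing")
    rows, skipped = [], []
    for name, subset in snp_sets.items():
        for thr in thresholds:
            inst = build_instrument(pairs, thr, snp_subset=subset, name=name)
            if inst.is_empty:
                skipped.append((name, thr))
                continue
            rows.append(gtx_association(inst, n_outcome, pseudo_r2_form).to_dict())
    table = pd.DataFrame(rows, columns=["set", "threshold", "m_snps", "alpha", "se",
                                        "z", "p", "pseudo_r2", "n_outcome"])
    return ScanResult(table=table, skipped=skipped)
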