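"""End-to-end orchestration of the cell-type-partitioned PRS analysis.

Stage order: variant QC (MAF/INFO) → greedy LD clumping → exclusion of the
APOE and MHC regions from the clumped pool → SNP→gene mapping with
one-SNP-per-gene deduplication → cell-type SNP sets → harmonization with
the outcome GWAS → (set × p-threshold) gtx scan with the whole-genome
score alongside → FWE control over the cell-type family → set-size-matched
permutation null for the top cell type → leave-set-out attenuation →
split-sample replication → APOE-inclusion sensitivity.

Region exclusion runs after clumping (regions are removed from the pruned
pool), which lets the sensitivity analysis re-include the same clumped
region SNPs without re-clumping.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import DataError
from .gene_annotation import build_cell_snp_sets, dedup_one_snp_per_gene, map_snps_to_genes
from .inference import (fwe_correct, leave_set_out, permutation_null,
                        replicate_and_combine, sensitivity_include_region)
from .prs_association import ScanResult, build_instrument, harmonize, threshold_scan
from .qc_clump import ClumpResult, Region, clump, exclude_regions, filter_variants
from .sumstats_io import CellTypeSets, DosageTable, RunConfig, SummaryStats

logger = logging.getLogger("cellprs")

WHOLE_GENOME = "whole_genome"


@dataclass
class PipelineResult:
    """Everything one pipeline run computes."""

    config: RunConfig
    n_input_snps: int
    n_after_qc: int
    clump: ClumpResult
    n_clumped: int
    n_after_region_exclusion: int
    snp_gene_map: object
    cell_snp_sets: dict
    pairs: pd.DataFrame
    scan: ScanResult
    cell_scan_fwe: pd.DataFrame
    whole_genome_scan: pd.DataFrame
    permutation: dict = field(default_factory=dict)
    leave_out: dict = field(default_factory=dict)
    replication: Optional[dict] = None
    sensitivity: Optional[dict] = None

    def best_cell_row(self) -> pd.Series:
        """The cell-type row with the largest |z| across thresholds."""
        t = self.cell_scan_fwe
        return t.loc[t["z"].abs().idxmax()]

    def cell_ranking(self, threshold: Optional[float] = None) -> pd.Series:
        """Cell types ranked by |z| (max over thresholds unless one is given)."""
        t = self.cell_scan_fwe
        if threshold is not None:
            t = t[t["threshold"] == threshold]
        return t.groupby("set")["z"].apply(lambda s: s.abs().max()).sort_values(ascending=False)


def run_pipeline(exposure: SummaryStats, outcome: SummaryStats, ld_ref: DosageTable,
                 genes, cell_sets: CellTypeSets, config: RunConfig,
                 n_outcome: Optional[int] = None,
                 outcome_discovery: Optional[SummaryStats] = None,
                 outcome_replication: Optional[SummaryStats] = None,
                 permute_target: Optional[str] = None,
                 run_sensitivity: bool = True) -> PipelineResult:
    """Run the full analysis against one (combined) outcome GWAS.

    ``permute_target`` names the cell type put through the permutation
    null; by default the cell type with the largest |z| after FWE is used.
    Discovery/replication outcome GWAS trigger the split-sample analysis.
    """
    n_outcome = n_outcome or outcome.n_total
    regions = [Region.from_tuple(r) for r in config.excluded_regions]

    qc = filter_variants(exposure, config.maf_min, config.info_min)
    clump_res = clump(qc, ld_ref, config.clump_window_kb, config.clump_r2_max,
                      missing_policy=config.missing_ld_policy)
    pruned = qc.subset(clump_res.retained)
    pruned_no_region = exclude_regions(pruned, regions)

    snp_meta = pruned_no_region.table[["SNP", "CHR", "BP"]]
    raw_map = map_snps_to_genes(snp_meta, genes, config.upstream_bp, config.downstream_bp,
                                strand_aware=config.strand_aware_windows)
    dedup = dedup_one_snp_per_gene(raw_map, pruned_no_region, genes=genes)
    cell_snps = build_cell_snp_sets(dedup, cell_sets)

    pairs_with_region = harmonize(pruned, outcome, config.palindromic_policy)
    region_mask = np.zeros(len(pairs_with_region), dtype=bool)
    for region in regions:
        region_mask |= ((pairs_with_region["chrom"].astype(str) == region.chrom)
                        & (pairs_with_region["pos"] >= region.start_bp)
                        & (pairs_with_region["pos"] <= region.end_bp)).to_numpy()
    pairs = pairs_with_region[~region_mask].reset_index(drop=True)

    snp_sets: dict = {WHOLE_GENOME: None}
    snp_sets.update({c: cell_snps[c] for c in cell_snps if cell_snps[c]})
    scan = threshold_scan(pairs, config.p_thresholds, snp_sets, n_outcome,
                          pseudo_r2_form=config.pseudo_r2_form)
    cell_rows = scan.table[scan.table["set"] != WHOLE_GENOME].reset_index(drop=True)
    wg_rows = scan.table[scan.table["set"] == WHOLE_GENOME].reset_index(drop=True)
    if cell_rows.empty:
        raise DataError("no cell-type instrument was non-empty")
    cell_fwe = fwe_correct(cell_rows, config.fwe_alpha, config.fwe_method)

    result = PipelineResult(
        config=config, n_input_snps=len(exposure), n_after_qc=len(qc),
        clump=clump_res, n_clumped=len(clump_res.retained),
        n_after_region_exclusion=len(pruned_no_region), snp_gene_map=dedup,
        cell_snp_sets=cell_snps, pairs=pairs, scan=scan, cell_scan_fwe=cell_fwe,
        whole_genome_scan=wg_rows,
    )

    # permutation null, matched for set size and threshold, on the top cell type
    target = permute_target or result.best_cell_row()["set"]
    mapped_universe = set(dedup.snp_ids())
    rng = substream(config.rng_seed, "permutation")
    for thr in config.p_thresholds:
        inst = build_instrument(pairs, thr, snp_subset=cell_snps.get(target, set()),
                                name=target)
        pool = pairs[pairs["snp_id"].isin(mapped_universe)]
        pool = pool[pool["p_exp"] < thr]
        if inst.is_empty or len(pool) <= len(inst):
            continue
        result.permutation[(target, thr)] = permutation_null(
            inst, pool, config.n_perm, rng, n_outcome, statistic=config.perm_statistic)
        result.leave_out[(target, thr)] = leave_set_out(
            pairs, cell_snps.get(target, set()), thr, n_outcome)

    if outcome_discovery is not None and outcome_replication is not None:
        pd_pairs = harmonize(pruned, outcome_discovery, config.palindromic_policy)
        pr_pairs = harmonize(pruned, outcome_replication, config.palindromic_policy)
        pd_pairs = pd_pairs[~pd_pairs["snp_id"].isin(
            set(pairs_with_region.loc[region_mask, "snp_id"]))].reset_index(drop=True)
        pr_pairs = pr_pairs[~pr_pairs["snp_id"].isin(
            set(pairs_with_region.loc[region_mask, "snp_id"]))].reset_index(drop=True)
        result.replication = replicate_and_combine(
            pd_pairs, pr_pairs, snp_sets, config.p_thresholds,
            outcome_discovery.n_total, outcome_replication.n_total,
            pairs_combined=pairs, n_combined=n_outcome,
            consistency_p=config.consistency_p)

    if run_sensitivity:
        apoe = next((r for r in regions if r.label == "APOE"), None)
        if apoe is not None:
            result.sensitivity = sensitivity_include_region(
                pairs_with_region, apoe, config.p_thresholds[-1], n_outcome)

    return result


def planted_signal_replicate(seed: int, arch=None, n_exposure: int = 20_000,
                             n_outcome: int = 20_000, n_ref: int = 2504,
                             n_perm: int = 1000) -> dict:
    """One full recovery experiment: simulate a study, run the pipeline,
    and summarise whether the planted target cell type was recovered.

    Returns the per-replicate success indicators (target ranked first,
    FWE-significant, permutation p_empirical < 0.05 at the target's best
    threshold, sign-consistent split-sample replication, complement of the
    leave-set-out fit still significant) plus the headline numbers.
    """
    from .synthetic_data import SimArchitecture, simulate_study

    arch = arch or SimArchitecture()
    study = simulate_study(arch, n_exposure=n_exposure, n_outcome=n_outcome,
                           n_ref=n_ref, seed=seed)
    config = RunConfig(rng_seed=seed, n_perm=n_perm)
    res = run_pipeline(study.exposure, study.outcome_combined, study.ld_ref,
                       study.genes, study.cell_sets, config,
                       outcome_discovery=study.outcome_discovery,
                       outcome_replication=study.outcome_replication,
                       permute_target=arch.target_cell_type)
    target = arch.target_cell_type
    t = res.cell_scan_fwe
    target_rows = t[t["set"] == target]
    best_thr = float(target_rows.loc[target_rows["z"].abs().idxmax(), "threshold"])
    perm = res.permutation.get((target, best_thr))
    meta = res.replication["meta"]
    ranking = res.cell_ranking()
    return {
        "target": target,
        "rank_first": ranking.index[0] == target,
        "fwe_significant": bool(target_rows["significant"].any()),
        "perm_p_empirical": perm.p_empirical if perm else float("nan"),
        "perm_z": perm.z_emp if perm else float("nan"),
        "perm_pass": bool(perm and perm.p_empirical < 0.05),
        "replicated": bool(meta.loc[meta["set"] == target, "consistent"].any()),
        "complement_significant": all(v.p_complement < 0.05
                                      for v in res.leave_out.values()),
        "z_target": float(ranking.iloc[0]) if ranking.index[0] == target
                    else float(ranking.loc[target]),
        "z_runner_up": float(ranking.iloc[1]),
        "alpha_whole_genome": float(res.whole_genome_scan["alpha"].iloc[-1]),
        "n_clumped": res.n_clumped,
        "n_gene_mapped": len(res.snp_gene_map),
        "apoe_delta_z": float(res.sensitivity["delta_z"]) if res.sensitivity else 0.0,
        "result": res,
    }
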