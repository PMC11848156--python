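"""SNP→gene mapping, one-SNP-per-gene deduplication, marker-gene
enrichment, and per-cell-type SNP set assembly.

SNPs map to protein-coding genes whose strand-aware proximity window they
fall in: 2 kb upstream and 0.5 kb downstream of the gene body by default,
with "upstream" meaning 5' of the gene (so the window is
[start−upstream, end+downstream] on the + strand and
[start−downstream, end+upstream] on the − strand).  A configuration switch
allows strand-agnostic windows.

Marker sets are derived from a gene × cell-type mean-expression table: a
gene is a marker of a cell type when its expression is enriched over the
background (log2 fold change > 0) and the per-gene upper-tail cumulative
hypergeometric test — does the gene claim a larger share of the cell type's
expression than of the background's? — survives Benjamini–Hochberg FDR
control within the cell type.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .sumstats_io import CellTypeSets, SummaryStats, chrom_sort_key

logger = logging.getLogger("cellprs")


class SnpGeneMap:
    """A mapping from SNP id to the set of gene ids it lies proximal to.

    Before deduplication a SNP may map to several genes; after
    :func:`dedup_one_snp_per_gene` each gene holds at most one SNP and each
    SNP belongs to exactly one gene.
    """

    def __init__(self, entries: dict[str, set], deduped: bool = False):
        self.entries = {s: frozenset(g) for s, g in entries.items() if g}
        self.deduped = deduped

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.entries

    def genes_of(self, snp_id: str) -> frozenset:
        return self.entries.get(snp_id, frozenset())

    def snp_ids(self) -> list[str]:
        return list(self.entries)

    def gene_to_snp(self) -> dict[str, str]:
        """Inverse map; only well-defined after deduplication."""
        if not self.deduped:
            raise DataError("gene_to_snp requires a deduplicated map")
        return {next(iter(genes)): snp for snp, genes in self.entries.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, g) for s, genes in self.entries.items() for g in sorted(genes)]
        return pd.DataFrame(rows, columns=["snp_id", "gene_id"])


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-(gene, cell type) marker evidence."""

    gene_id: str
    cell_type: str
    lfc: float
    p_hyper: float
    fdr: float


def _gene_window(gene, upstream_bp: int, downstream_bp: int, strand_aware: bool) -> tuple[int, int]:
    if not strand_aware or gene.strand == "+":
        return gene.start - upstream_bp, gene.end + downstream_bp
    return gene.start - downstream_bp, gene.end + upstream_bp


def map_snps_to_genes(snps: pd.DataFrame, genes, upstream_bp: int, downstream_bp: int,
                      strand_aware: bool = True) -> SnpGeneMap:
    """Map each SNP to every protein-coding gene whose window contains it.

    ``snps`` needs columns SNP, CHR, BP.  SNPs mapping to no gene are left
    out of the map (and thereby out of score construction).
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise DataError("windows must be non-negative")
    entries: dict[str, set] = {}
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): grp.sort_values("BP") for c, grp in snps.groupby("CHR")
    }
    for gene in genes:
        if not gene.protein_coding:
            continue
        grp = by_chrom.get(gene.chrom)
        if grp is None:
            continue
        lo, hi = _gene_window(gene, upstream_bp, downstream_bp, strand_aware)
        pos = grp["BP"].to_numpy()
        a = np.searchsorted(pos, lo, side="left")
        b = np.searchsorted(pos, hi, side="right")
        for snp in grp["SNP"].iloc[a:b]:
            entries.setdefault(str(snp), set()).add(gene.gene_id)
    return SnpGeneMap(entries, deduped=False)


def _distance_to_body(pos: int, gene) -> int:
    if gene.start <= pos <= gene.end:
        return 0
    return gene.start - pos if pos < gene.start else pos - gene.end


def dedup_one_snp_per_gene(snp_map: SnpGeneMap, exposure: SummaryStats,
                           genes=None) -> SnpGeneMap:
    """Collapse the map so each gene keeps exactly one SNP and vice versa.

    Per gene, the SNP with the smallest exposure p-value is retained (ties
    broken by smaller (chrom, pos)).  A SNP still claimed by several genes
    afterwards is assigned to its nearest gene by distance to the gene body
    (tie: smaller gene start).
    """
    t = exposure.table
    info = {r.SNP: (float(r.P), chrom_sort_key(r.CHR), int(r.BP))
            for r in t[["SNP", "P", "CHR", "BP"]].itertuples(index=False)}
    missing = [s for s in snp_map.entries if s not in info]
    if missing:
        raise DataError(f"mapped SNP(s) missing from exposure: {missing[:5]}")

    per_gene: dict[str, list[str]] = {}
    for snp, gene_ids in snp_map.entries.items():
        for g in gene_ids:
            per_gene.setdefault(g, []).append(snp)

    chosen: dict[str, str] = {}  # gene -> snp
    for g, snp_list in per_gene.items():
        chosen[g] = min(snp_list, key=lambda s: info[s])

    snp_claims: dict[str, set] = {}
    for g, s in chosen.items():
        snp_claims.setdefault(s, set()).add(g)

    gene_by_id = {g.gene_id: g for g in genes} if genes is not None else None
    entries: dict[str, set] = {}
    for snp, claimed in snp_claims.items():
        if len(claimed) == 1 or gene_by_id is None:
            winner = min(claimed)  # deterministic when gene records unavailable
        else:
            pos = info[snp][2]
            winner = min(claimed,
                         key=lambda gid: (_distance_to_body(pos, gene_by_id[gid]),
                                          gene_by_id[gid].start, gid))
        entries[snp] = {winner}
    return SnpGeneMap(entries, deduped=True)


def score_marker_enrichment(expr: pd.DataFrame, background: pd.Series,
                            fdr_alpha: float = 0.05, count_scale: float = 100.0,
                            pseudocount_rel: float = 1e-9) -> CellTypeSets:
    """Derive cell-type marker sets from a gene × cell-type expression table.

    For gene *g* in cell type *c* the upper-tail cumulative hypergeometric
    asks whether *g* accounts for a larger share of expression in *c* than
    in the background: with scaled integer counts, the population pools the
    cell-type column and the background column, successes are gene *g*'s
    counts, and the draw is the cell-type column.  Benjamini–Hochberg is
    applied across genes within each cell type; markers require lfc > 0 and
    FDR < ``fdr_alpha``.  All-zero expression rows are skipped with a
    warning.
    """
    expr = expr.astype(float)
    background = background.reindex(expr.index).astype(float)
    zero = (expr.sum(axis=1) == 0) & (background.fillna(0) == 0)
    if zero.any():
        warnings.warn(f"skipping {int(zero.sum())} all-zero expression row(s)")
        expr = expr[~zero]
        background = background[~zero]

    eps = pseudocount_rel * float(expr.to_numpy().mean() if expr.size else 1.0)
    lfc = np.log2((expr.add(eps)).div(background + eps, axis=0))

    counts = np.rint(expr.to_numpy() * count_scale).astype(np.int64)
    bg_counts = np.rint(background.to_numpy() * count_scale).astype(np.int64)
    bg_total = int(bg_counts.sum())

    sets: dict[str, set] = {}
    rows = []
    for j, cell in enumerate(expr.columns):
        col = counts[:, j]
        col_total = int(col.sum())
        M = col_total + bg_total                      # population size
        n_draw = col_total                            # draws: the cell-type column
        pvals = np.ones(len(expr))
        for i in range(len(expr)):
            K = int(col[i] + bg_counts[i])            # successes: gene's pooled counts
            k = int(col[i])
            pvals[i] = sps.hypergeom.sf(k - 1, M, K, n_draw) if M > 0 else 1.0
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
        is_marker = (lfc.iloc[:, j].to_numpy() > 0) & (fdr < fdr_alpha)
        sets[cell] = set(expr.index[is_marker])
        for i, gene in enumerate(expr.index):
            rows.append((gene, cell, float(lfc.iloc[i, j]), float(pvals[i]), float(fdr[i])))
    stats_df = pd.DataFrame(rows, columns=["gene_id", "cell_type", "lfc", "p_hyper", "fdr"])
    empty = [c for c in expr.columns if not sets[c]]
    if empty:
        logger.info("score_marker_enrichment: no markers for %s", ", ".join(map(str, empty)))
    return CellTypeSets(sets, stats=stats_df, allow_empty=True)


def hypergeom_upper_tail(k: int, M: int, K: int, n: int) -> float:
    """Exact upper-tail hypergeometric P(X >= k) by direct summation.

    Retained as a readable reference form; production code calls scipy's
    ``hypergeom.sf`` which matches this to numerical precision.
    """
    total = 0.0
    denom = math.comb(M, n)
    for j in range(max(k, 0), min(K, n) + 1):
        total += math.comb(K, j) * math.comb(M - K, n - j) / denom
    return min(1.0, total)


def build_cell_snp_sets(snp_map: SnpGeneMap, sets: CellTypeSets) -> dict[str, frozenset]:
    """Assemble each cell type's SNP set from its marker genes.

    A SNP appears in every cell type whose marker set contains its gene.
    Cell types with no mapped SNPs are retained with cardinality 0 and
    flagged via a log entry (downstream association skips them).
    """
    if not snp_map.deduped:
        raise DataError("build_cell_snp_sets requires a deduplicated SNP-gene map")
    gene_to_snp = snp_map.gene_to_snp()
    out: dict[str, frozenset] = {}
    for cell, genes in sets.items():
        snps = frozenset(gene_to_snp[g] for g in genes if g in gene_to_snp)
        if not snps:
            logger.info("cell type %s: empty SNP set (flagged, excluded from association)", cell)
        out[cell] = snps
    return out
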