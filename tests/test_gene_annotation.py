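"""SNP→gene windows, deduplication, marker enrichment, cell SNP sets."""
import math

import numpy as np
import pandas as pd
import pytest

import cellprs as cp
from cellprs.gene_annotation import hypergeom_upper_tail
from conftest import make_sumstats


def gene(gid, chrom, start, end, strand="+", coding=True):
    return cp.GeneRecord(gene_id=gid, chrom=chrom, start=start, end=end,
                         strand=strand, protein_coding=coding)


def snp_frame(entries):
    return pd.DataFrame(entries, columns=["SNP", "CHR", "BP"])


class TestMapSnpsToGenes:
    GENES = [gene("Gp", "1", 10_000, 12_000, "+"),
             gene("Gm", "1", 50_000, 52_000, "-"),
             gene("Gnc", "1", 90_000, 92_000, "+", coding=False)]

    @pytest.mark.parametrize("pos,expected", [
        (10_000 - 2000, {"Gp"}),     # exactly at upstream cutoff (+)
        (10_000 - 2001, set()),      # one bp beyond
        (12_000 + 500, {"Gp"}),      # exactly at downstream cutoff (+)
        (12_000 + 501, set()),       # one bp beyond
        (11_000, {"Gp"}),            # inside the body
        (52_000 + 2000, {"Gm"}),     # minus strand: upstream is 3' side
        (52_000 + 2001, set()),
        (50_000 - 500, {"Gm"}),      # minus strand: downstream is 5' side
        (50_000 - 501, set()),
        (91_000, set()),             # non-coding genes are ineligible
    ])
    def test_window_boundaries(self, pos, expected):
        m = cp.map_snps_to_genes(snp_frame([("rs1", "1", pos)]), self.GENES, 2000, 500)
        assert set(m.genes_of("rs1")) == expected

    def test_matches_exhaustive_interval_enumeration(self, rng):
        genes = [gene(f"G{i}", "1", int(s), int(s) + 1000,
                      "-" if i % 3 == 0 else "+")
                 for i, s in enumerate(rng.integers(1_000, 100_000, 5))]
        snps = [(f"rs{i}", "1", int(p)) for i, p in enumerate(rng.integers(1, 105_000, 15))]
        m = cp.map_snps_to_genes(snp_frame(snps), genes, 2000, 500)
        for sid, _, pos in snps:
            expected = set()
            for g in genes:
                lo, hi = ((g.start - 2000, g.end + 500) if g.strand == "+"
                          else (g.start - 500, g.end + 2000))
                if lo <= pos <= hi:
                    expected.add(g.gene_id)
            assert set(m.genes_of(sid)) == expected

    def test_monotone_in_window_size(self, rng):
        genes = [gene(f"G{i}", "1", int(s), int(s) + 500)
                 for i, s in enumerate(rng.integers(1_000, 50_000, 4))]
        snps = [(f"rs{i}", "1", int(p)) for i, p in enumerate(rng.integers(1, 55_000, 30))]
        small = cp.map_snps_to_genes(snp_frame(snps), genes, 1000, 200)
        large = cp.map_snps_to_genes(snp_frame(snps), genes, 5000, 2000)
        for sid in small.snp_ids():
            assert small.genes_of(sid) <= large.genes_of(sid)

    def test_strand_agnostic_switch(self):
        m = cp.map_snps_to_genes(snp_frame([("rs1", "1", 50_000 - 2000)]),
                                 self.GENES, 2000, 500, strand_aware=False)
        assert set(m.genes_of("rs1")) == {"Gm"}


class TestDedup:
    GENES = [gene("G1", "1", 1000, 2000), gene("G2", "1", 2500, 3500)]

    def stats(self, rows):
        return make_sumstats(rows)

    def test_single_snp_gene_unchanged(self):
        m = cp.SnpGeneMap({"rs1": {"G1"}})
        s = self.stats([("rs1", "1", 1500, "A", "G", 0.1, 0.05, 0.1, 0.2, 0.95)])
        d = cp.dedup_one_snp_per_gene(m, s, genes=self.GENES)
        assert d.gene_to_snp() == {"G1": "rs1"}

    def test_smallest_p_wins(self):
        m = cp.SnpGeneMap({"rsA": {"G1"}, "rsB": {"G1"}, "rsC": {"G1"}})
        s = self.stats([
            ("rsA", "1", 1100, "A", "G", 0.1, 0.05, 0.1, 0.2, 0.95),
            ("rsB", "1", 1200, "A", "G", 0.1, 0.05, 0.01, 0.2, 0.95),
            ("rsC", "1", 1300, "A", "G", 0.1, 0.05, 0.5, 0.2, 0.95),
        ])
        d = cp.dedup_one_snp_per_gene(m, s, genes=self.GENES)
        assert d.gene_to_snp() == {"G1": "rsB"}

    def test_equal_p_breaks_tie_by_position(self):
        m = cp.SnpGeneMap({"rsA": {"G1"}, "rsB": {"G1"}})
        s = self.stats([
            ("rsB", "1", 1100, "A", "G", 0.1, 0.05, 0.1, 0.2, 0.95),
            ("rsA", "1", 1200, "A", "G", 0.1, 0.05, 0.1, 0.2, 0.95),
        ])
        d = cp.dedup_one_snp_per_gene(m, s, genes=self.GENES)
        assert d.gene_to_snp() == {"G1": "rsB"}

    def test_residual_multi_gene_snp_goes_to_nearest(self):
        # rsX is the best SNP for both genes; it sits inside G1's body
        m = cp.SnpGeneMap({"rsX": {"G1", "G2"}})
        s = self.stats([("rsX", "1", 1900, "A", "G", 0.1, 0.05, 0.001, 0.2, 0.95)])
        d = cp.dedup_one_snp_per_gene(m, s, genes=self.GENES)
        assert d.genes_of("rsX") == {"G1"}

    def test_retained_count_equals_genes_with_snps(self, rng):
        genes = [gene(f"G{i}", "1", 10_000 * (i + 1), 10_000 * (i + 1) + 2000)
                 for i in range(6)]
        rows, entries = [], {}
        for i in range(30):
            g = genes[int(rng.integers(0, 6))]
            pos = int(g.start + rng.integers(0, 2000))
            rows.append((f"rs{i}", "1", pos, "A", "G", 0.1, 0.05,
                         float(rng.uniform(0, 1)), 0.2, 0.95))
            entries[f"rs{i}"] = {g.gene_id}
        # positions may collide; deduplicate rows by position
        seen, clean = set(), []
        for r in rows:
            if r[2] not in seen:
                seen.add(r[2])
                clean.append(r)
        entries = {r[0]: entries[r[0]] for r in clean}
        s = make_sumstats(clean)
        d = cp.dedup_one_snp_per_gene(cp.SnpGeneMap(entries), s, genes=genes)
        genes_hit = {next(iter(g)) for g in entries.values()}
        assert len(d) == len(genes_hit)

    def test_missing_exposure_snp_is_data_error(self):
        m = cp.SnpGeneMap({"rsX": {"G1"}})
        s = self.stats([("rsY", "1", 1000, "A", "G", 0.1, 0.05, 0.1, 0.2, 0.95)])
        with pytest.raises(cp.DataError):
            cp.dedup_one_snp_per_gene(m, s, genes=self.GENES)


class TestMarkerEnrichment:
    def test_exclusively_expressed_gene_is_marker_with_minimal_p(self):
        expr = pd.DataFrame(
            {"A": [50.0, 1.0, 1.0], "B": [0.0, 1.0, 1.0]},
            index=["g_marker", "g1", "g2"])
        bg = expr.mean(axis=1)
        sets = cp.score_marker_enrichment(expr, bg)
        assert "g_marker" in sets["A"] and "g_marker" not in sets["B"]
        st = sets.stats
        p_marker_a = st[(st.gene_id == "g_marker") & (st.cell_type == "A")].p_hyper.iloc[0]
        assert p_marker_a == st[st.cell_type == "A"].p_hyper.min()

    def test_uniform_expression_gives_empty_sets(self):
        expr = pd.DataFrame(np.ones((20, 4)), index=[f"g{i}" for i in range(20)],
                            columns=list("ABCD"))
        sets = cp.score_marker_enrichment(expr, expr.mean(axis=1))
        assert all(len(sets[c]) == 0 for c in sets)

    def test_tail_probabilities_equal_exact_combinatorial_sums(self, rng):
        expr = pd.DataFrame(rng.integers(0, 20, size=(12, 4)).astype(float),
                            index=[f"g{i}" for i in range(12)], columns=list("ABCD"))
        expr.iloc[0] += 1  # keep every row nonzero
        bg = expr.mean(axis=1)
        sets = cp.score_marker_enrichment(expr, bg, count_scale=1.0)
        st = sets.stats.set_index(["gene_id", "cell_type"])
        counts = np.rint(expr.to_numpy()).astype(int)
        bg_counts = np.rint(bg.to_numpy()).astype(int)
        for j, cell in enumerate(expr.columns):
            col_total = counts[:, j].sum()
            M = int(col_total + bg_counts.sum())
            for i, g in enumerate(expr.index):
                K = int(counts[i, j] + bg_counts[i])
                expected = hypergeom_upper_tail(int(counts[i, j]), M, K, int(col_total))
                assert st.loc[(g, cell), "p_hyper"] == pytest.approx(expected, rel=1e-9)

    def test_label_shuffle_shrinks_planted_marker_sets(self, rng):
        n_genes, n_types = 40, 4
        expr = pd.DataFrame(rng.uniform(0.5, 1.5, size=(n_genes, n_types)),
                            index=[f"g{i}" for i in range(n_genes)],
                            columns=[f"C{j}" for j in range(n_types)])
        for i in range(10):  # plant 10 strong markers of C0
            expr.iloc[i, 0] *= 20
        bg = expr.mean(axis=1)
        planted = len(cp.score_marker_enrichment(expr, bg)["C0"])
        sizes = []
        for _ in range(100):
            shuffled = expr.copy()
            for i in range(n_genes):
                shuffled.iloc[i] = rng.permutation(shuffled.iloc[i].to_numpy())
            sizes.append(len(cp.score_marker_enrichment(shuffled, shuffled.mean(axis=1))["C0"]))
        assert np.mean(sizes) < planted

    def test_all_zero_row_skipped_with_warning(self):
        expr = pd.DataFrame({"A": [5.0, 0.0], "B": [1.0, 0.0]}, index=["g1", "gz"])
        with pytest.warns(UserWarning):
            sets = cp.score_marker_enrichment(expr, pd.Series({"g1": 3.0, "gz": 0.0}))
        assert "gz" not in sets.stats["gene_id"].values


class TestBuildCellSnpSets:
    def deduped_map(self):
        return cp.SnpGeneMap({"rs1": {"G1"}, "rs2": {"G2"}, "rs3": {"G3"}}, deduped=True)

    def test_disjoint_marker_sets_give_disjoint_snp_sets(self):
        sets = cp.CellTypeSets({"A": {"G1"}, "B": {"G2", "G3"}})
        out = cp.build_cell_snp_sets(self.deduped_map(), sets)
        assert out == {"A": frozenset({"rs1"}), "B": frozenset({"rs2", "rs3"})}

    def test_shared_marker_gene_lands_in_both_sets(self):
        sets = cp.CellTypeSets({"A": {"G1"}, "B": {"G1", "G2"}})
        out = cp.build_cell_snp_sets(self.deduped_map(), sets)
        assert "rs1" in out["A"] and "rs1" in out["B"]

    def test_unmapped_marker_set_is_flagged_empty(self):
        sets = cp.CellTypeSets({"A": {"G1"}, "Z": {"G99"}})
        out = cp.build_cell_snp_sets(self.deduped_map(), sets)
        assert out["Z"] == frozenset()

    def test_requires_deduped_map(self):
        raw = cp.SnpGeneMap({"rs1": {"G1", "G2"}})
        with pytest.raises(cp.DataError):
            cp.build_cell_snp_sets(raw, cp.CellTypeSets({"A": {"G1"}}))

    def test_dedup_never_grows_sets(self, small_study, small_pipeline):
        universe = set(small_pipeline.snp_gene_map.snp_ids())
        for cell, snps in small_pipeline.cell_snp_sets.items():
            assert snps <= universe
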