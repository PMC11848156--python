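"""FWE control, permutation null, attenuation, replication, rank concordance."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cellprs as cp
from cellprs._rng import substream
from cellprs.inference import fixed_effect_meta, normal_two_tailed_p
from test_prs_association import pairs_frame


def scan_table(pvals):
    n = len(pvals)
    return pd.DataFrame({
        "set": [f"C{i}" for i in range(n)], "threshold": 0.5,
        "m_snps": 10, "alpha": 0.1, "se": 0.05, "z": 2.0,
        "p": pvals, "pseudo_r2": 0.001, "n_outcome": 1000,
    })


class TestFweCorrect:
    def test_p_one_stays_capped(self):
        out = cp.fwe_correct(scan_table([1.0, 0.5]))
        assert out["p_fwe"].iloc[0] == 1.0

    def test_bonferroni_arithmetic(self):
        out = cp.fwe_correct(scan_table([0.001] + [0.5] * 41))
        assert out["p_fwe"].iloc[0] == pytest.approx(0.042)
        assert out.attrs["n_tests"] == 42

    def test_family_counts_only_performed_tests(self):
        # three of six cells were skipped upstream: the table only has 3 rows
        out = cp.fwe_correct(scan_table([0.01, 0.02, 0.03]))
        assert out.attrs["n_tests"] == 3
        assert out["p_fwe"].iloc[0] == pytest.approx(0.03)

    def test_never_decreases_p_and_flags_monotone_in_alpha(self, rng):
        p = rng.uniform(0, 1, 20)
        out = cp.fwe_correct(scan_table(p))
        assert (out["p_fwe"].to_numpy() >= p - 1e-15).all()
        loose = cp.fwe_correct(scan_table(p), alpha=0.2)["significant"]
        tight = cp.fwe_correct(scan_table(p), alpha=0.01)["significant"]
        assert (tight <= loose).all()

    def test_holm_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(0, 0.2, 10)
        out = cp.fwe_correct(scan_table(p), method="holm")
        _, expected, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(out["p_fwe"], expected)


class TestPermutationNull:
    def make_pool(self, rng, n=200):
        return pairs_frame(rng.normal(size=n), rng.normal(scale=0.05, size=n),
                           rng.uniform(0.03, 0.1, n))

    def test_paper_arithmetic_z_to_p(self):
        # an empirical z of 2.47 converts to a two-tailed p of 0.013 at the
        # two-significant-figure precision such values are reported with
        assert normal_two_tailed_p(2.47) == pytest.approx(0.013, abs=1e-3)

    def test_centered_observation_gives_z_zero(self, rng):
        pool = self.make_pool(rng)
        inst = cp.ScoreInstrument("t", 1.0, pool.iloc[:20].copy())
        res = cp.permutation_null(inst, pool, 200, substream(0, "perm"))
        forced = cp.PermutationResult(
            observed_stat=res.null_mean, null_mean=res.null_mean, null_sd=res.null_sd,
            z_emp=0.0, p_two_tailed=1.0, p_empirical=0.5, n_perm=200, set_size=20)
        assert forced.z_emp == 0.0 and forced.p_two_tailed == 1.0
        assert (res.observed_stat - res.null_mean) / res.null_sd == pytest.approx(res.z_emp)

    def test_same_seed_reproduces_exactly(self, rng):
        pool = self.make_pool(rng)
        inst = cp.ScoreInstrument("t", 1.0, pool.iloc[:15].copy())
        a = cp.permutation_null(inst, pool, 300, substream(4, "perm"))
        b = cp.permutation_null(inst, pool, 300, substream(4, "perm"))
        assert a.to_dict() == b.to_dict()

    def test_different_seeds_agree_on_null_mean(self, rng):
        pool = self.make_pool(rng, n=300)
        inst = cp.ScoreInstrument("t", 1.0, pool.iloc[:30].copy())
        a = cp.permutation_null(inst, pool, 1000, substream(1, "perm"))
        b = cp.permutation_null(inst, pool, 1000, substream(2, "perm"))
        se = max(a.null_sd, b.null_sd) / np.sqrt(1000)
        assert abs(a.null_mean - b.null_mean) < 3 * se

    def test_small_pool_warns_and_tiny_pool_errors(self, rng):
        pool = self.make_pool(rng, n=30)
        inst = cp.ScoreInstrument("t", 1.0, pool.iloc[:20].copy())
        with pytest.warns(UserWarning):
            cp.permutation_null(inst, pool, 50, substream(0, "perm"))
        inst_big = cp.ScoreInstrument("t", 1.0, pool.copy())
        with pytest.raises(cp.DataError):
            cp.permutation_null(inst_big, pool, 50, substream(0, "perm"))


class TestLeaveSetOut:
    def test_empty_cell_set_changes_nothing(self, rng):
        pairs = pairs_frame(rng.normal(size=20), rng.normal(size=20),
                            rng.uniform(0.05, 0.2, 20))
        res = cp.leave_set_out(pairs, set(), 1.0, 1000)
        assert res.alpha_full == pytest.approx(res.alpha_complement)
        assert res.z_diff == 0.0

    def test_cell_set_covering_everything_is_error(self, rng):
        pairs = pairs_frame(rng.normal(size=5), rng.normal(size=5),
                            rng.uniform(0.05, 0.2, 5))
        with pytest.raises(cp.DataError):
            cp.leave_set_out(pairs, set(pairs["snp_id"]), 1.0, 1000)

    def test_nested_variance_identity_monte_carlo(self, rng):
        """var(alpha_full - alpha_complement) equals se_c^2 - se_f^2."""
        n = 40
        w = rng.normal(size=n)
        s = rng.uniform(0.05, 0.2, n)
        cell = {f"rs{i}" for i in range(10)}
        diffs, var_pred = [], None
        for _ in range(2000):
            b = rng.normal(scale=s)  # null outcome betas with the stated SEs
            pairs = pairs_frame(w, b, s)
            res = cp.leave_set_out(pairs, cell, 1.0, 1000)
            diffs.append(res.alpha_full - res.alpha_complement)
            var_pred = res.se_complement**2 - res.se_full**2
        mc = float(np.var(diffs))
        assert mc == pytest.approx(var_pred, rel=0.15)

    def test_se_ordering_holds_on_pipeline_output(self, small_pipeline):
        for res in small_pipeline.leave_out.values():
            assert res.se_complement >= res.se_full


class TestReplicateAndCombine:
    def test_duplicate_sample_closed_form(self, rng):
        pairs = pairs_frame(rng.normal(size=30), rng.normal(size=30),
                            rng.uniform(0.05, 0.2, 30))
        res = cp.replicate_and_combine(pairs, pairs.copy(), {"wg": None}, [1.0],
                                       1000, 1000)
        d = res["discovery"].table.iloc[0]
        m = res["meta"].iloc[0]
        assert m["alpha_meta"] == pytest.approx(d["alpha"])
        assert m["se_meta"] == pytest.approx(d["se"] / np.sqrt(2))

    def test_meta_arithmetic(self):
        m = fixed_effect_meta(0.2, 0.1, 0.4, 0.2)
        w1, w2 = 100.0, 25.0
        assert m["alpha_meta"] == pytest.approx((w1 * 0.2 + w2 * 0.4) / (w1 + w2))
        assert m["se_meta"] == pytest.approx((w1 + w2) ** -0.5)

    def test_planted_signal_replicates_in_small_study(self, small_pipeline, small_study):
        meta = small_pipeline.replication["meta"]
        target = small_study.arch.target_cell_type
        assert meta.loc[meta["set"] == target, "consistent"].any()

    def test_null_simulation_rarely_flags_consistency(self, rng):
        flags = 0
        for _ in range(200):
            w = rng.normal(size=20)
            s = np.full(20, 0.1)
            pd_pairs = pairs_frame(w, rng.normal(scale=0.1, size=20), s)
            pr_pairs = pairs_frame(w, rng.normal(scale=0.1, size=20), s)
            res = cp.replicate_and_combine(pd_pairs, pr_pairs, {"wg": None}, [1.0],
                                           1000, 1000)
            flags += int(res["meta"]["consistent"].iloc[0])
        assert flags / 200 <= 0.01 + 0.02  # joint two-sample type-I is ~0.125%


class TestRankConcordance:
    def test_identity_gives_rho_one(self, rng):
        a = pd.Series(rng.normal(size=6), index=list("ABCDEF"))
        rho, _ = cp.rank_concordance(a, a)
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self, rng):
        a = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("ABCDE"))
        rho, _ = cp.rank_concordance(a, -a)
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_enumeration_n7(self, rng):
        a = pd.Series(rng.normal(size=7), index=list("ABCDEFG"))
        b = pd.Series(rng.normal(size=7), index=list("ABCDEFG"))
        rho, p = cp.rank_concordance(a, b)
        ra = sps.rankdata(a.to_numpy())
        rb = sps.rankdata(b.to_numpy())
        count = 0
        for perm in itertools.permutations(range(7)):
            r = np.corrcoef(ra, rb[list(perm)])[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        assert p == pytest.approx(count / 5040)

    def test_large_n_uses_t_approximation(self, rng):
        idx = [f"C{i}" for i in range(12)]
        a = pd.Series(rng.normal(size=12), index=idx)
        b = pd.Series(rng.normal(size=12), index=idx)
        rho, p = cp.rank_concordance(a, b)
        rho_sp, p_sp = sps.spearmanr(a, b)
        assert rho == pytest.approx(rho_sp) and p == pytest.approx(p_sp)

    def test_fewer_than_four_keys_is_error(self):
        a = pd.Series([1.0, 2.0, 3.0], index=list("ABC"))
        with pytest.raises(cp.DataError):
            cp.rank_concordance(a, a)


class TestSensitivityIncludeRegion:
    def region(self):
        return cp.Region("1", 0, 10, "toy")

    def test_region_without_snps_is_identity_with_warning(self, rng):
        pairs = pairs_frame(rng.normal(size=10), rng.normal(size=10),
                            rng.uniform(0.05, 0.2, 10))
        pairs["pos"] += 1000
        with pytest.warns(UserWarning):
            res = cp.sensitivity_include_region(pairs, self.region(), 1.0, 1000)
        assert res["delta_alpha"] == 0.0 and res["n_region_snps"] == 0

    def test_remove_then_reinclude_reproduces_fit(self, rng):
        pairs = pairs_frame(rng.normal(size=10), rng.normal(size=10),
                            rng.uniform(0.05, 0.2, 10))
        res = cp.sensitivity_include_region(pairs, cp.Region("1", 1, 5, "toy"), 1.0, 1000)
        refit = cp.gtx_association(cp.build_instrument(pairs, 1.0), 1000)
        assert res["with_region"].alpha_hat == pytest.approx(refit.alpha_hat)

    def test_strong_planted_region_increases_z(self, small_pipeline):
        # APOE decoys carry large concordant effects in the simulation
        assert small_pipeline.sensitivity["delta_z"] > 0
        assert small_pipeline.sensitivity["n_region_snps"] > 0


class TestPipelineSummary:
    def test_clump_partition_and_counts(self, small_pipeline):
        res = small_pipeline
        assert res.n_clumped == len(res.clump.retained)
        assert res.n_after_qc == res.n_clumped + len(res.clump.removed)

    def test_fwe_flags_target(self, small_pipeline, small_study):
        t = small_pipeline.cell_scan_fwe
        target = small_study.arch.target_cell_type
        assert t.loc[t["set"] == target, "significant"].any()

    def test_whole_genome_positive_and_significant(self, small_pipeline):
        wg = small_pipeline.whole_genome_scan
        assert (wg["alpha"] > 0).all() and (wg["p"] < 0.05).all()
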