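import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import comb

from chromstress import (
    DECriteria,
    bh_adjust,
    count_degs,
    hypergeometric_enrichment,
    nb_test,
    poscounts_size_factors,
    size_factors,
)
from chromstress.models import GeneSetCollection, InputError, NormalizationError


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        x = np.array([[10, 5, 3], [10, 5, 3]])
        np.testing.assert_allclose(size_factors(x), [1.0, 1.0])

    def test_doubled_sample_splits_geometrically(self):
        x = np.array([[10, 20, 30], [20, 40, 60]])
        np.testing.assert_allclose(size_factors(x), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_global_scaling_preserves_factor_ratios(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(20, (3, 50)) + 1
        f1, f2 = size_factors(x), size_factors(7 * x)
        np.testing.assert_allclose(f2 / f1, np.full(3, f2[0] / f1[0]), rtol=1e-9)

    def test_no_common_positive_gene_is_error(self):
        x = np.array([[1, 0], [0, 1]])
        with pytest.raises(NormalizationError):
            size_factors(x)

    def test_poscounts_robust_to_composition_shift(self):
        # sample B doubles depth AND has one huge gene; median ratio ignores it
        rng = np.random.default_rng(1)
        a = rng.poisson(50, 100) + 1
        b = 2 * a
        b[0] *= 50
        f = poscounts_size_factors(np.vstack([a, b]))
        np.testing.assert_allclose(f[1] / f[0], 2.0, rtol=0.05)


def bh_oracle(p):
    """Brute-force step-up rule: padj_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for rank_pos, i in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        out[i] = min(1.0, min(candidates))
    return out


class TestBHAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_degenerate_inputs(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])

    def test_matches_oracle_on_all_small_permutations(self):
        base = [0.01, 0.04, 0.3, 0.72, 0.9, 0.04]
        for perm in itertools.permutations(base):
            np.testing.assert_allclose(bh_adjust(perm), bh_oracle(perm), rtol=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_statsmodels_reference(self, p):
        from statsmodels.stats.multitest import multipletests

        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-10, atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(2)
        p = rng.random(200)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestNbTest:
    def test_identical_counts_give_null_result(self):
        counts = np.tile(np.array([[4, 7, 0]]), (10, 1))
        res = nb_test(counts, ["a"] * 5 + ["b"] * 5, mode="per_cell")
        np.testing.assert_allclose(res["log2fc"], 0.0)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_matches_scipy_rank_sum_without_ties(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(10_000, 1_000_000, size=(40, 5))
        groups = np.array(["a"] * 20 + ["b"] * 20)
        res = nb_test(counts, groups, mode="per_cell")
        norm = counts / poscounts_size_factors(counts)[:, None]
        for j in range(5):
            ref = stats.mannwhitneyu(
                norm[20:, j], norm[:20, j], alternative="two-sided", use_continuity=False
            ).pvalue
            assert res["p"][j] == pytest.approx(ref, rel=1e-6)

    def test_recovers_planted_log2fc(self):
        """Planted 4x induction (log2FC 2) at baseline mean 20, dispersion 0.1,
        100 cells per group is estimated within +/-0.25 on average."""
        rng = np.random.default_rng(4)
        mu = np.exp(rng.normal(np.log(15), 1.0, 500))
        idx = rng.choice(500, 30, replace=False)
        mu[idx] = 20.0
        lfc = np.zeros(500)
        lfc[idx] = 2.0
        la = rng.gamma(10, np.tile(mu, (100, 1)) / 10)
        lb = rng.gamma(10, np.tile(mu * 2.0**lfc, (100, 1)) / 10)
        counts = np.vstack([rng.poisson(la), rng.poisson(lb)])
        res = nb_test(counts, ["a"] * 100 + ["b"] * 100, mode="per_cell")
        assert abs(res["log2fc"].to_numpy()[idx].mean() - 2.0) < 0.25

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(5)
        mu = np.exp(rng.normal(np.log(15), 1.0, 2000))
        lam = rng.gamma(10, np.tile(mu, (200, 1)) / 10)
        counts = rng.poisson(lam)
        res = nb_test(counts, ["a"] * 100 + ["b"] * 100, mode="per_cell")
        assert 0.03 < (res["p"] < 0.05).mean() < 0.07
        assert (res["padj"] < 0.05).sum() <= 2

    def test_pseudobulk_wald_detects_planted_effects(self):
        rng = np.random.default_rng(6)
        mu = np.exp(rng.normal(np.log(100), 1.0, 800))
        lfc = np.zeros(800)
        lfc[:50] = 2.0
        la = rng.gamma(10, np.tile(mu, (4, 1)) / 10)
        lb = rng.gamma(10, np.tile(mu * 2.0**lfc, (4, 1)) / 10)
        counts = np.vstack([rng.poisson(la), rng.poisson(lb)])
        res = nb_test(counts, ["a"] * 4 + ["b"] * 4, mode="pseudobulk")
        assert res["is_deg"][:50].sum() >= 45
        assert (res["p"][50:] < 0.05).mean() < 0.12

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            nb_test(np.ones((4, 3), dtype=int), ["a"] * 4)

    def test_non_integral_counts_rejected(self):
        with pytest.raises(InputError):
            nb_test(np.full((4, 2), 1.5), ["a", "a", "b", "b"])


class TestCountDegs:
    def test_empty_result(self):
        empty = pd.DataFrame(columns=["log2fc", "padj"])
        assert count_degs(empty) == (0, 0, 0)

    def test_rule_application(self):
        res = pd.DataFrame(
            {"log2fc": [1.0, 0.2, -1.0], "padj": [0.01, 0.01, 0.2]}
        )
        assert count_degs(res, DECriteria(fc_min=1.5, alpha=0.05)) == (1, 1, 0)

    def test_monotone_in_both_criteria(self):
        rng = np.random.default_rng(7)
        res = pd.DataFrame({"log2fc": rng.normal(0, 1, 300), "padj": rng.random(300)})
        strict = count_degs(res, DECriteria(fc_min=2.0, alpha=0.01))[0]
        for fc_min, alpha in [(1.5, 0.01), (2.0, 0.05), (1.5, 0.05)]:
            assert count_degs(res, DECriteria(fc_min=fc_min, alpha=alpha))[0] >= strict


class TestEnrichment:
    def test_exact_hypergeometric_tail(self):
        universe = [f"u{i}" for i in range(100)]
        geneset = GeneSetCollection(sets={"S": universe[:10]})
        degs = universe[:5] + universe[50:55]  # overlap 5 of 10
        res = hypergeometric_enrichment(degs, universe, geneset)
        expected = sum(
            comb(10, k) * comb(90, 10 - k) for k in range(5, 11)
        ) / comb(100, 10)
        assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-10)
        assert res["overlap"].iloc[0] == 5

    def test_zero_overlap_near_one_and_full_set_exactly_one(self):
        universe = [f"u{i}" for i in range(50)]
        sets = GeneSetCollection(sets={"tiny": universe[:2], "all": list(universe)})
        res = hypergeometric_enrichment(universe[10:20], universe, sets).set_index("set")
        assert res.loc["tiny", "p"] > 0.5
        assert res.loc["all", "p"] == pytest.approx(1.0)

    def test_deg_outside_universe_rejected(self):
        with pytest.raises(InputError):
            hypergeometric_enrichment(["x"], ["a", "b"], GeneSetCollection(sets={"S": ["a"]}))
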