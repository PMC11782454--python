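"""Rank-sum tests, BH adjustment, impact/combined scores, hit classes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, mannwhitneyu

from co2fit.stats import (
    StatsError,
    between_condition_test,
    bh_adjust,
    classify_hits,
    combined_score,
    compare_conditions,
    condition_gene_test,
    impact_score,
    wilcoxon_rank_sum,
)

from conftest import IMPACT_EXAMPLES


def enumerate_rank_sum_p(x, y, alternative="two-sided"):
    """Exact two-sided rank-sum p by complete enumeration (oracle)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()

    def u_stat(idx):
        rx = ranks[list(idx)].sum()
        return rx - n * (n + 1) / 2

    u_obs = u_stat(range(n))
    us = np.array([u_stat(c) for c in itertools.combinations(range(len(pooled)), n)])
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    if alternative == "two-sided":
        return min(1.0, 2 * min(p_le, p_ge))
    raise NotImplementedError


class TestWilcoxon:
    def test_complete_separation_of_two_vs_two(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_groups_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        assert wilcoxon_rank_sum(x, x) > 0.9

    def test_exact_branch_equals_enumeration(self):
        """Exact permutation p equals complete enumeration, all tie-free
        group sizes with n + m <= 10."""
        rng = np.random.default_rng(12)
        for n in range(1, 10):
            for m in range(1, 11 - n):
                pooled = rng.permutation(rng.uniform(size=n + m) + np.arange(n + m))
                x, y = pooled[:n], pooled[n:]
                assert wilcoxon_rank_sum(x, y) == pytest.approx(
                    enumerate_rank_sum_p(x, y), abs=1e-12
                ), (n, m)

    def test_exact_close_to_normal_approximation(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=10), rng.normal(0.5, 1, size=10)
        exact = wilcoxon_rank_sum(x, y)
        approx = float(
            mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
        assert exact == pytest.approx(approx, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            wilcoxon_rank_sum([], [1.0])


def bh_oracle(p):
    """Independent step-up implementation."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestBH:
    def test_hand_computed_step_up(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_monotone_in_order_statistics_and_capped(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj <= 1.0)
        assert np.all(adj >= p)

    def test_invalid_inputs(self):
        with pytest.raises(StatsError):
            bh_adjust([0.1, np.nan])
        with pytest.raises(StatsError):
            bh_adjust([0.0])


class TestConditionGeneTest:
    def test_target_matching_controls_is_null(self):
        rng = np.random.default_rng(1)
        controls = rng.normal(0, 0.2, size=50)
        med = np.median(controls)
        df = pd.DataFrame(
            {
                "target_id": ["ctrl"] * 50 + ["geneA"] * 5,
                "fitness": np.concatenate([controls, med + np.linspace(-0.01, 0.01, 5)]),
            }
        )
        out = condition_gene_test(df).set_index("target_id")
        assert out.loc["geneA", "p"] > 0.5

    def test_depleted_target_detected(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "target_id": ["ctrl"] * 50 + ["geneA"] * 5,
                "fitness": np.concatenate([rng.normal(0, 0.2, 50), np.full(5, -3.0)]),
            }
        )
        out = condition_gene_test(df).set_index("target_id")
        assert out.loc["geneA", "p"] < 0.01

    def test_null_pvalues_roughly_uniform(self):
        """Label permutations of a null target give ~uniform p (KS test)."""
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(500):
            scores = rng.normal(size=55)
            df = pd.DataFrame(
                {"target_id": ["geneA"] * 5 + ["ctrl"] * 50, "fitness": scores}
            )
            ps.append(condition_gene_test(df)["p"].iloc[0])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_few_guide_targets_get_nan(self):
        df = pd.DataFrame(
            {"target_id": ["ctrl"] * 10 + ["geneA"], "fitness": np.arange(11.0)}
        )
        out = condition_gene_test(df, min_guides=2).set_index("target_id")
        assert np.isnan(out.loc["geneA", "p_adj"])

    def test_missing_controls_rejected(self):
        df = pd.DataFrame({"target_id": ["geneA"] * 5, "fitness": np.arange(5.0)})
        with pytest.raises(StatsError, match="ctrl"):
            condition_gene_test(df)


class TestBetweenConditionTest:
    def test_identical_score_sets_null(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=30)
        a = pd.DataFrame({"target_id": "g", "fitness": scores})
        out = between_condition_test(a, a.copy())
        assert out["p"].iloc[0] > 0.9

    def test_complete_separation_five_vs_five(self):
        a = pd.DataFrame({"target_id": "g", "fitness": [-2.4, -2.5, -2.6, -2.55, -2.45]})
        b = pd.DataFrame({"target_id": "g", "fitness": [2.5, 2.6, 2.4, 2.65, 2.55]})
        out = between_condition_test(a, b)
        assert out["p"].iloc[0] == pytest.approx(2 / 252, abs=1e-12)

    def test_pure_null_screen_controls_fdr(self):
        """BH at 0.05 on a null screen calls at most ~5% of targets."""
        rng = np.random.default_rng(13)
        n_targets = 2000
        rows_a, rows_b = [], []
        for i in range(n_targets):
            rows_a.append(pd.DataFrame({"target_id": f"g{i}", "fitness": rng.normal(size=20)}))
            rows_b.append(pd.DataFrame({"target_id": f"g{i}", "fitness": rng.normal(size=15)}))
        out = between_condition_test(pd.concat(rows_a), pd.concat(rows_b))
        assert (out["p_adj"] < 0.05).mean() <= 0.05


class TestScores:
    def test_published_worked_examples(self):
        for locus, (y0, x0, printed) in IMPACT_EXAMPLES.items():
            assert impact_score(x0, y0) == pytest.approx(printed, abs=0.01), locus

    def test_identity_line_gives_zero(self):
        assert impact_score(1.7, 1.7) == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(21)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert np.allclose(impact_score(a, b), -impact_score(b, a))

    def test_combined_score(self):
        assert combined_score(2.0, 0.01) == pytest.approx(4.0)
        assert combined_score(-3.0, 0.001) == pytest.approx(-9.0)
        assert combined_score(5.0, 1.0) == 0.0
        with pytest.raises(StatsError):
            combined_score(1.0, 0.0)

    def test_hit_classification_boundaries(self):
        assert classify_hits(-1.5) == "depleted"
        assert classify_hits(0.0) == "neutral"
        assert classify_hits(1.0001) == "enriched"
        assert classify_hits(1.0) == "neutral"
        assert classify_hits(-1.0) == "neutral"
        assert list(classify_hits([-2, 0, 2])) == ["depleted", "neutral", "enriched"]


class TestCompareConditions:
    def test_assembled_table(self):
        a = pd.DataFrame({"target_id": ["g1", "g2"], "fitness": [-3.20, 0.64]})
        b = pd.DataFrame({"target_id": ["g1", "g2"], "fitness": [1.95, -4.54]})
        test = pd.DataFrame({"target_id": ["g1", "g2"], "p": [0.01, 0.5], "p_adj": [0.02, 0.5]})
        out = compare_conditions(a, b, test).set_index("target_id")
        assert out.loc["g1", "impact"] == pytest.approx(3.64, abs=0.01)
        assert out.loc["g2", "impact"] == pytest.approx(-3.66, abs=0.01)
        assert out.loc["g1", "combined"] == pytest.approx(
            out.loc["g1", "impact"] * -np.log10(0.02)
        )
        assert out.loc["g1", "class_a"] == "depleted"
        assert out.loc["g1", "class_b"] == "enriched"
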