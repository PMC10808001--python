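"""Rank statistics, effect sizes and the summary-statistic t test."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from amphihelix.stats import (
    cles,
    compare_by_localization,
    holm_adjust,
    kruskal_wallis,
    pairwise_rank_sum,
    rank_sum_pair,
    unpaired_t,
    unpaired_t_raw,
    TestResult,
)


class TestKruskalWallis:
    def test_two_group_hand_ranks(self):
        # ranks 1..6, R1=6, R2=15: H = 12/(6*7) * (36/3 + 225/3) - 21
        res = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.statistic == pytest.approx(12 / 42 * (12 + 75) - 21)
        assert res.statistic == pytest.approx(3.857, abs=1e-3)

    def test_exact_p_matches_exhaustive_enumeration(self):
        groups = {"a": [1.0, 2, 3], "b": [4.0, 5, 6]}
        res = kruskal_wallis(groups, n_exact=10)
        # independent enumeration over all C(6,3) assignments
        values = np.array([1, 2, 3, 4, 5, 6], float)
        h_obs = res.statistic
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(combo)] = True
            h = sps.kruskal(values[mask], values[~mask]).statistic
            total += 1
            count += h >= h_obs - 1e-12
        assert res.p_value == pytest.approx(count / total)
        assert res.p_value == pytest.approx(0.1)

    def test_identical_constant_groups_convention(self):
        res = kruskal_wallis({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_label_order_invariance(self, rng):
        g = {k: rng.normal(size=15).tolist() for k in "abc"}
        res1 = kruskal_wallis(g)
        res2 = kruskal_wallis({k: g[k] for k in reversed(list(g))})
        assert res1.statistic == pytest.approx(res2.statistic)
        assert res1.p_value == pytest.approx(res2.p_value)

    def test_agrees_with_scipy_on_ties(self, rng):
        g = {k: rng.integers(0, 5, size=25).astype(float) for k in "abc"}
        res = kruskal_wallis(g)
        ref = sps.kruskal(*g.values())
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [1.0], "b": []})

    def test_exact_vs_asymptotic_agreement_large_n(self, rng):
        """Monte-Carlo permutation and chi-square p agree within 0.02 for
        tie-free samples of total size >= 30."""
        for _ in range(10):
            g = {k: rng.normal(loc=i * 0.3, size=12) for i, k in enumerate("abc")}
            asym = kruskal_wallis(g)
            perm = kruskal_wallis(g, n_perm=4000, seed=7)
            assert abs(asym.p_value - perm.p_value) < 0.02


class TestPairwise:
    def test_complete_separation(self):
        results = pairwise_rank_sum({"a": [1.0, 2, 3], "b": [4.0, 5, 6]})
        r = results[0]
        assert r.effect_size == 0.0
        assert r.median_diff == -3.0
        assert r.p_value == pytest.approx(0.1)  # exact two-sided, n=(3,3)

    def test_group_against_itself(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r = pairwise_rank_sum({"a": x, "b": list(x)})[0]
        assert r.effect_size == pytest.approx(0.5)
        assert r.median_diff == 0.0

    def test_cles_complementarity_tie_free(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=30)
        assert cles(a, b) + cles(b, a) == pytest.approx(1.0)

    def test_cles_with_ties(self):
        assert cles([1, 2], [2, 3]) == pytest.approx((0 + 0.5 + 0 + 0) / 4)

    def test_exact_p_matches_enumeration(self):
        # n=(3,3), complete separation: only 2 of C(6,3)=20 rank splits are
        # as extreme, two-sided p = 2/20
        _, p, method = rank_sum_pair([10.0, 11, 12], [1.0, 2, 3])
        assert method == "exact"
        assert p == pytest.approx(0.1)

    def test_asymptotic_used_for_large_samples(self, rng):
        _, _, method = rank_sum_pair(rng.normal(size=30), rng.normal(size=30))
        assert method == "asymptotic"


class TestHolm:
    def test_adjusted_at_least_raw_and_monotone(self, rng):
        results = [
            TestResult(0.0, p, "x") for p in rng.uniform(size=12)
        ]
        holm_adjust(results)
        by_raw = sorted(results, key=lambda r: r.p_value)
        adj = [r.adjusted_p for r in by_raw]
        assert all(r.adjusted_p >= r.p_value for r in results)
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))


class TestUnpairedT:
    def test_identical_summaries(self):
        res = unpaired_t(5.0, 1.0, 3, 5.0, 1.0, 3)
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_replicate_mean_shift_reproduces_small_p(self):
        """Two replicate means 0.32 apart with sub-0.05 scatter at n=3 are
        distinguished at p ~ 5e-4 (pooled two-tailed)."""
        res = unpaired_t(10.96, 0.04, 3, 11.28, 0.03, 3)
        assert res.p_value == pytest.approx(0.0005, abs=2.5e-4)
        assert res.p_value < 0.001

    def test_doubling_n_decreases_p(self):
        p1 = unpaired_t(1.0, 1.0, 5, 1.5, 1.0, 5).p_value
        p2 = unpaired_t(1.0, 1.0, 10, 1.5, 1.0, 10).p_value
        assert p2 < p1

    def test_welch_df_smaller_than_pooled(self):
        pooled = unpaired_t(0, 1, 5, 1, 3, 8)
        welch = unpaired_t(0, 1, 5, 1, 3, 8, welch=True)
        assert welch.extra["df"] < pooled.extra["df"]

    def test_raw_vector_interface_matches_scipy(self, rng):
        x, y = rng.normal(size=8), rng.normal(1.0, 1.0, size=9)
        res = unpaired_t_raw(x, y, welch=True)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_degenerate_zero_variance(self):
        res = unpaired_t(2.0, 0.0, 3, 2.0, 0.0, 3)
        assert res.p_value == 1.0


class TestCompareByLocalization:
    def test_single_group_rejected(self):
        import pandas as pd

        frame = pd.DataFrame({"label": ["a"] * 5, "H": range(5)})
        with pytest.raises(ValueError):
            compare_by_localization(frame, ["H"])

    def test_report_structure_and_planted_effect(self, rng):
        import pandas as pd

        frame = pd.DataFrame({
            "label": ["mito"] * 40 + ["other"] * 40,
            "basic_fraction": np.r_[rng.normal(0.35, 0.05, 40),
                                    rng.normal(0.18, 0.05, 40)],
            "muH": rng.normal(0.65, 0.05, 80),
        })
        report = compare_by_localization(frame, ["basic_fraction", "muH"])
        assert report["groups"] == {"mito": 40, "other": 40}
        assert report["properties"]["basic_fraction"]["omnibus"]["p_value"] < 0.001
        pw = report["properties"]["basic_fraction"]["pairwise"][0]
        assert 0.0 <= pw["cles"] <= 1.0 and pw["adjusted_p"] >= pw["p_value"]
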