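"""Rank statistics against brute-force and library cross-check oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cep_planner.demand_stats import (
    dunn_bonferroni,
    durbin_watson_statistic,
    kruskal_wallis,
    ols_with_durbin_watson,
    spearman,
)


def kw_statistic_oracle(groups):
    """Tie-corrected H recomputed from first principles (independent path)."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    i = 0
    srt = pooled[order]
    while i < len(srt):
        j = i
        while j < len(srt) and srt[j] == srt[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2  # mid-rank, 1-based
        i = j
    n = len(pooled)
    h, off = 0.0, 0
    for g in groups:
        r = ranks[off : off + len(g)]
        h += r.sum() ** 2 / len(g)
        off += len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    return h / (1 - np.sum(t**3 - t) / (n**3 - n))


def kw_permutation_p(groups):
    """Exact permutation p-value by enumerating group assignments."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    observed = kw_statistic_oracle(groups)
    n_extreme = n_total = 0
    for perm in itertools.permutations(range(len(pooled))):
        values = pooled[list(perm)]
        out, off = [], 0
        for s in sizes:
            out.append(values[off : off + s])
            off += s
        n_total += 1
        if kw_statistic_oracle(out) >= observed - 1e-12:
            n_extreme += 1
    return n_extreme / n_total


class TestKruskalWallis:
    def test_identical_groups_no_signal(self):
        res = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert res.H == 0.0
        assert res.p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            groups = [
                rng.integers(0, 6, size=rng.integers(3, 9)).astype(float)
                for _ in range(rng.integers(2, 5))
            ]
            if all(np.all(np.concatenate(groups) == groups[0][0]) for _ in [0]):
                continue
            ours = kruskal_wallis(groups)
            H, p = sps.kruskal(*groups)
            assert ours.H == pytest.approx(H)
            assert ours.p == pytest.approx(p)

    def test_statistic_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            groups = [
                rng.integers(0, 9, size=rng.integers(2, 5)).astype(float)
                for _ in range(rng.integers(2, 4))
            ]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            assert kruskal_wallis(groups).H == pytest.approx(
                kw_statistic_oracle(groups)
            )

    @pytest.mark.parametrize(
        "groups",
        [
            [[1.0, 5.0, 2.0], [8.0, 9.0], [3.0, 4.0, 7.0]],
            [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]],
            [[2.0, 4.0], [1.0, 3.0, 5.0], [6.0, 7.0, 8.0]],
        ],
    )
    def test_chi_square_close_to_exact_permutation_in_tail(self, groups):
        """In the decision-relevant tail (p <= 0.1) the chi-square reference
        tracks the exact permutation distribution on n <= 8 to within 0.02;
        mid-distribution p-values are cruder (documented limitation)."""
        exact = kw_permutation_p(groups)
        approx = kruskal_wallis(groups).p
        assert abs(approx - exact) < 0.02

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(-50, 50), min_size=2, max_size=5),
            min_size=2,
            max_size=4,
        )
    )
    def test_monotone_transform_invariance(self, groups):
        # integer inputs keep exp(v/25) strictly monotone in float arithmetic
        transformed = [[math.exp(v / 25) for v in g] for g in groups]
        a = kruskal_wallis(groups)
        b = kruskal_wallis(transformed)
        assert a.H == pytest.approx(b.H, abs=1e-8)


class TestDunn:
    def test_hand_computed_mean_ranks(self):
        # pooled ranks: 1..6; mean ranks 1.5 / 3.5 / 5.5
        groups = [[1, 2], [3, 4], [5, 6]]
        res = dunn_bonferroni(groups)
        n = 6
        var = n * (n + 1) / 12
        expected_z = (1.5 - 3.5) / math.sqrt(var * (1 / 2 + 1 / 2))
        assert res[0].z == pytest.approx(expected_z)
        assert res[0].p_adj == pytest.approx(min(1, res[0].p_raw * 3))

    def test_identical_groups_all_one(self):
        res = dunn_bonferroni([[2, 2], [2, 2], [2, 2]])
        assert all(d.p_adj == 1.0 for d in res)

    def test_adjusted_never_below_raw(self, density_groups):
        for d in dunn_bonferroni(density_groups):
            assert d.p_adj >= d.p_raw
            assert d.p_adj <= 1.0

    def test_single_comparison_unadjusted(self):
        res = dunn_bonferroni([[1, 2, 3], [4, 5, 6]], m=1)
        assert res[0].p_adj == pytest.approx(res[0].p_raw)


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.rho == pytest.approx(1.0)

    def test_sign_flip_on_negation(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.5]
        assert spearman(x, y).rho == pytest.approx(-spearman(x, [-v for v in y]).rho)

    def test_rank_invariance(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0, 9.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.5, 0.5]
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        assert spearman(x, y).rho == pytest.approx(spearman(rx, ry).rho)

    def test_ties_match_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.integers(0, 5, size=12).astype(float)
            y = rng.integers(0, 5, size=12).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            ours = spearman(x, y)
            rho, p = sps.spearmanr(x, y)
            assert ours.rho == pytest.approx(rho)
            assert ours.p == pytest.approx(p, abs=1e-8)

    def test_constant_sequence_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_weekday_fixture(self, weekday_totals):
        res = spearman(weekday_totals["weekday"], weekday_totals["count"])
        assert round(res.rho, 2) == -0.39


class TestOLSDurbinWatson:
    def test_exact_linear_fit(self):
        x = np.arange(10, dtype=float)
        res = ols_with_durbin_watson(x, 2 * x)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_matches_statsmodels(self, weekday_totals):
        import statsmodels.api as sm
        from statsmodels.stats.stattools import durbin_watson

        x = weekday_totals["weekday"].to_numpy(float)
        y = weekday_totals["count"].to_numpy(float)
        ours = ols_with_durbin_watson(x, y)
        model = sm.OLS(y, sm.add_constant(x)).fit()
        assert ours.r_squared == pytest.approx(model.rsquared)
        assert ours.adj_r_squared == pytest.approx(model.rsquared_adj)
        assert ours.p_slope == pytest.approx(model.pvalues[1])
        assert ours.dw_stat == pytest.approx(durbin_watson(model.resid))

    def test_white_noise_dw_near_two(self):
        rng = np.random.default_rng(3)
        x = np.arange(200, dtype=float)
        y = rng.standard_normal(200)
        res = ols_with_durbin_watson(x, y)
        assert 1.7 < res.dw_stat < 2.3
        assert res.dw_p > 0.05  # no autocorrelation evidence

    def test_autocorrelated_residuals_flagged(self):
        rng = np.random.default_rng(5)
        x = np.arange(150, dtype=float)
        e = np.zeros(150)
        for i in range(1, 150):
            e[i] = 0.8 * e[i - 1] + rng.standard_normal()
        res = ols_with_durbin_watson(x, e)
        assert res.dw_stat < 1.5
        assert res.dw_p < 0.05

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            ols_with_durbin_watson([1, 1, 1], [1, 2, 3])

    def test_dw_statistic_bounds(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            e = rng.standard_normal(20)
            assert 0 <= durbin_watson_statistic(e) <= 4
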