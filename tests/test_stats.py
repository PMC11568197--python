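"""Rank tests, effect sizes, contingency suite and Spearman screen,
cross-checked against brute-force enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spafnirs import (
    contingency_suite,
    kendall_tau_b_2x2,
    mann_whitney_rb,
    signed_rank_rb,
    spearman_screen,
    table1_battery,
    welch_t,
)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def u_oracle(g1, g2):
    """O(n1*n2) pair count of (g2 > g1) with half credit for ties."""
    u = 0.0
    for b in g2:
        for a in g1:
            u += 1.0 if b > a else (0.5 if b == a else 0.0)
    return u


def chi2_oracle(table):
    table = np.asarray(table, float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    e = rows * cols / table.sum()
    return float(((table - e) ** 2 / e).sum())


def tau_b_oracle(x, y):
    """Full O(N^2) concordance enumeration with tie corrections."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    m = n * (n - 1) / 2
    denom = np.sqrt((m - tx) * (m - ty))
    return (conc - disc) / denom if denom > 0 else np.nan


def signed_rank_rb_oracle(d):
    """Hand-ranked (T+ - T-)/(T+ + T-)."""
    d = np.asarray(d, float)
    d = d[d != 0]
    order = np.argsort(np.abs(d), kind="stable")
    ranks = np.empty(len(d))
    sabs = np.abs(d)[order]
    i = 0
    while i < len(d):
        j = i
        while j < len(d) and sabs[j] == sabs[i]:
            j += 1
        ranks[order[i:j]] = np.mean(np.arange(i, j) + 1)
        i = j
    tp = ranks[d > 0].sum()
    tm = ranks[d < 0].sum()
    return (tp - tm) / (tp + tm)


# ---------------------------------------------------------------------------

class TestSignedRank:
    def test_all_positive_differences(self):
        res = signed_rank_rb(np.arange(1.0, 11.0))
        assert res.r_rb == pytest.approx(1.0)
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)
        assert res.p_value < 0.01

    def test_symmetric_differences_cancel(self):
        res = signed_rank_rb(np.array([1.0, -1.0, 2.0, -2.0]))
        assert res.r_rb == pytest.approx(0.0)

    def test_hand_ranked_example(self):
        # |d| ranks: 1->1, 2->2, 3->3, -4->4 ; T+ = 6, T- = 4
        res = signed_rank_rb(np.array([1.0, 2.0, 3.0, -4.0]))
        assert res.r_rb == pytest.approx(0.2)
        assert res.statistic == pytest.approx(4.0)  # min(T+, T-)

    def test_all_zero_differences_degenerate(self):
        res = signed_rank_rb(np.zeros(6))
        assert res.degenerate

    @given(st.lists(st.integers(-50, 50), min_size=5, max_size=25))
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle(self, vals):
        d = np.array(vals, float)
        if np.all(d == 0):
            return
        res = signed_rank_rb(d)
        assert res.r_rb == pytest.approx(signed_rank_rb_oracle(d), abs=1e-10)
        assert abs(res.r_rb) <= 1.0


class TestWelch:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = welch_t(x, x)
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_separated_groups_significant(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(3, 1, 7)
        res = welch_t(x, y)
        assert res["p"] < 0.001
        # closed-form cross-check
        se = np.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
        assert res["t"] == pytest.approx((x.mean() - y.mean()) / se)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(1, 2, 9)
        a, b = welch_t(x, y), welch_t(y, x)
        assert a["t"] == pytest.approx(-b["t"])
        assert a["p"] == pytest.approx(b["p"])

    def test_zero_variance_flagged(self):
        res = welch_t(np.full(4, 2.0), np.full(5, 2.0))
        assert res["degenerate"]


class TestMannWhitney:
    def test_sex_by_subgroup_effect_size(self):
        # subgroup 1: 8 female (0), 2 male (1); subgroup 2: 2 female, 5 male
        values = np.array([0] * 8 + [1] * 2 + [0] * 2 + [1] * 5, float)
        labels = np.array([1] * 10 + [2] * 7)
        res = mann_whitney_rb(values, labels)
        assert res.r_rb == pytest.approx(0.514, abs=5e-4)
        assert res.statistic == pytest.approx(53.0)

    def test_full_separation(self):
        res = mann_whitney_rb(
            np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
            np.array(["a", "a", "a", "b", "b", "b"]),
        )
        assert abs(res.r_rb) == pytest.approx(1.0)
        assert (res.ci_low, res.ci_high) == (res.r_rb, res.r_rb)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_rb(np.array([1.0, 2.0]), np.array([1, 1]))

    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=14),
        st.lists(st.integers(0, 8), min_size=2, max_size=14),
    )
    @settings(max_examples=60, deadline=None)
    def test_u_matches_pair_enumeration(self, l1, l2):
        g1, g2 = np.array(l1, float), np.array(l2, float)
        values = np.concatenate([g1, g2])
        labels = np.array([1] * len(g1) + [2] * len(g2))
        res = mann_whitney_rb(values, labels)
        assert res.statistic == pytest.approx(u_oracle(g1, g2), abs=1e-10)


class TestContingency:
    def test_published_table(self):
        res = contingency_suite(8, 2, 2, 5)
        assert res.chi2 == pytest.approx(4.496, abs=1e-3)
        assert res.df == 1
        assert res.p == pytest.approx(0.034, abs=1e-3)
        assert res.log_or == pytest.approx(-2.303, abs=1e-3)
        assert res.or_ci_low == pytest.approx(-4.559, abs=1e-3)
        assert res.or_ci_high == pytest.approx(-0.046, abs=1e-3)
        assert res.tau_b == pytest.approx(-0.514, abs=1e-3)
        assert res.tau_z == pytest.approx(-2.057, abs=1e-2)

    def test_independent_table(self):
        res = contingency_suite(5, 5, 5, 5)
        assert res.chi2 == pytest.approx(0.0)
        assert res.log_or == pytest.approx(0.0)
        assert res.tau_b == pytest.approx(0.0)

    def test_zero_cell_flags_log_or(self):
        res = contingency_suite(6, 0, 2, 4)
        assert not res.log_or_defined
        assert np.isnan(res.log_or)
        assert np.isfinite(res.chi2)
        assert np.isfinite(res.tau_b)

    def test_row_swap_negates_or_and_tau(self):
        a = contingency_suite(8, 2, 2, 5)
        b = contingency_suite(2, 5, 8, 2)
        assert b.log_or == pytest.approx(-a.log_or)
        assert b.tau_b == pytest.approx(-a.tau_b)
        assert b.chi2 == pytest.approx(a.chi2)

    @given(
        st.tuples(*[st.integers(1, 9)] * 4)
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_brute_force_oracles(self, counts):
        a, b, c, d = counts
        res = contingency_suite(a, b, c, d)
        assert res.chi2 == pytest.approx(chi2_oracle([[a, b], [c, d]]), abs=1e-10)
        x = np.repeat([1.0, 0.0, 1.0, 0.0], [a, b, c, d])
        y = np.repeat([1, 1, 2, 2], [a, b, c, d])
        assert res.tau_b == pytest.approx(tau_b_oracle(x, y), abs=1e-10)

    def test_closed_form_tau_equals_enumeration_large(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(0, 11, 4)
            if (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            x = np.repeat([1.0, 0.0, 1.0, 0.0], [a, b, c, d])
            y = np.repeat([1, 1, 2, 2], [a, b, c, d])
            assert kendall_tau_b_2x2(a, b, c, d) == pytest.approx(
                tau_b_oracle(x, y), abs=1e-10
            )


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        res = spearman_screen({"up": (x, x**3), "down": (x, -x - 1)})
        assert res[0].spearman_r == pytest.approx(1.0)
        assert res[1].spearman_r == pytest.approx(-1.0)

    def test_rank_then_pearson_oracle(self, rng):
        from scipy.stats import rankdata

        x = rng.normal(size=34)
        y = 0.5 * x + rng.normal(size=34)
        res = spearman_screen({"xy": (x, y)})[0]
        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.spearman_r == pytest.approx(oracle, abs=1e-10)

    def test_constant_covariate_flagged(self):
        res = spearman_screen({"c": (np.ones(10), np.arange(10.0))})[0]
        assert np.isnan(res.spearman_r)


class TestTable1Battery:
    def test_returns_one_row_per_covariate_with_sex_matching_published(self):
        import pandas as pd

        cov = pd.DataFrame({
            "sex": [0.0] * 8 + [1.0] * 2 + [0.0] * 2 + [1.0] * 5,
            "weight": np.linspace(1200, 2400, 17),
        })
        labels = np.array([1] * 10 + [2] * 7)
        out = table1_battery(cov, labels)
        assert set(out["parameter"]) == {"sex", "weight"}
        sex_row = out[out.parameter == "sex"].iloc[0]
        assert sex_row["r_rb"] == pytest.approx(0.514, abs=5e-4)
        assert sex_row["U"] == pytest.approx(53.0)
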