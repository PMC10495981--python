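"""Welch t, ANOVA + Sidak: closed forms and independent references."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ielquant.stats import (
    anova_sidak,
    compare_groups,
    sidak_adjust,
    student_t_test,
    welch_t_test,
)


def welch_reference(a, b):
    """Hand-coded Welch t / Welch-Satterthwaite df / two-sided p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


class TestWelch:
    A = [2.1, 2.5, 3.0, 2.8]
    B = [3.9, 4.4, 4.1, 5.0, 4.6]

    def test_matches_closed_form_to_six_decimals(self):
        res = welch_t_test(self.A, self.B)
        t, df, p = welch_reference(self.A, self.B)
        assert res.statistic == pytest.approx(t, abs=1e-6)
        assert res.df == pytest.approx(df, abs=1e-6)
        assert res.p_value == pytest.approx(p, abs=1e-6)

    def test_swapping_samples_negates_t_preserves_p(self):
        r1 = welch_t_test(self.A, self.B)
        r2 = welch_t_test(self.B, self.A)
        assert r2.statistic == pytest.approx(-r1.statistic)
        assert r2.p_value == pytest.approx(r1.p_value)

    def test_identical_samples_t_zero_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = welch_t_test(x, x)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            welch_t_test([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_student_variant_uses_pooled_df(self):
        res = student_t_test(self.A, self.B)
        assert res.df == len(self.A) + len(self.B) - 2


class TestSidak:
    def test_closed_form_m3(self):
        assert sidak_adjust(0.05, 3) == pytest.approx(1 - 0.95**3)
        assert sidak_adjust(0.05, 3) == pytest.approx(0.142625)

    def test_single_comparison_unchanged(self):
        assert sidak_adjust(0.03, 1) == pytest.approx(0.03)

    def test_monotone_in_m_and_p(self):
        ps = np.linspace(0.0, 1.0, 21)
        for m in (1, 2, 5):
            adj = [sidak_adjust(float(p), m) for p in ps]
            assert all(x <= y + 1e-15 for x, y in zip(adj, adj[1:]))
        for p in (0.01, 0.05, 0.2):
            by_m = [sidak_adjust(p, m) for m in range(1, 8)]
            assert all(x <= y + 1e-15 for x, y in zip(by_m, by_m[1:]))

    def test_adjusted_never_below_raw(self):
        for p in (0.001, 0.05, 0.5):
            for m in (1, 3, 6):
                assert sidak_adjust(p, m) >= p - 1e-15

    @settings(derandomize=True, deadline=None)
    @given(p=st.floats(0.0, 1.0), m=st.integers(1, 50))
    def test_adjustment_stays_a_probability(self, p, m):
        adj = sidak_adjust(p, m)
        assert 0.0 <= adj <= 1.0
        assert adj >= p - 1e-12


class TestAnovaSidak:
    def groups(self):
        rng = np.random.default_rng(99)
        return [rng.normal(0, 1, 8), rng.normal(0, 1, 8), rng.normal(2.5, 1, 8)]

    def test_omnibus_matches_statsmodels_to_six_decimals(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        groups = self.groups()
        df = pd.DataFrame(
            {"value": np.concatenate(groups),
             "group": np.repeat(["a", "b", "c"], [len(g) for g in groups])}
        )
        table = sm.stats.anova_lm(ols("value ~ C(group)", data=df).fit())
        res = anova_sidak(groups, labels=["a", "b", "c"])
        assert res[0].statistic == pytest.approx(table["F"].iloc[0], abs=1e-6)
        assert res[0].p_value == pytest.approx(table["PR(>F)"].iloc[0], abs=1e-6)

    def test_pairwise_pooled_t_matches_hand_formula(self):
        groups = self.groups()
        res = anova_sidak(groups, labels=["a", "b", "c"])
        n = [len(g) for g in groups]
        mse = sum((ni - 1) * np.var(g, ddof=1) for ni, g in zip(n, groups)) / (sum(n) - 3)
        from scipy.stats import t as tdist

        pair = next(r for r in res[1:] if (r.group_a, r.group_b) == ("a", "c"))
        t_ref = (groups[0].mean() - groups[2].mean()) / math.sqrt(mse * (1 / n[0] + 1 / n[2]))
        p_ref = 2 * tdist.sf(abs(t_ref), sum(n) - 3)
        assert pair.statistic == pytest.approx(t_ref, abs=1e-9)
        assert pair.p_value == pytest.approx(p_ref, abs=1e-9)
        assert pair.adjusted_p == pytest.approx(sidak_adjust(p_ref, 3), abs=1e-12)

    def test_comparisons_restrict_sidak_family(self):
        groups = self.groups()
        res = anova_sidak(groups, labels=["a", "b", "c"], comparisons=[("a", "c")])
        assert len(res) == 2  # omnibus + the single pair
        assert res[1].adjusted_p == pytest.approx(res[1].p_value)

    def test_fewer_than_three_groups_directed_to_t_test(self):
        with pytest.raises(ValueError, match="t_test"):
            anova_sidak([[1.0, 2.0], [2.0, 3.0]])


class TestCompareGroups:
    def test_auto_two_groups_uses_welch(self):
        df = pd.DataFrame({"value": [1, 2, 3, 4, 5, 7, 8, 9.0], "group": list("aaaabbbb")})
        out = compare_groups(df)
        assert list(out["method"]) == ["welch_t"]

    def test_auto_three_groups_uses_anova(self):
        df = pd.DataFrame(
            {"value": np.arange(12.0) + np.tile([0, 5, 10], 4), "group": list("abc") * 4}
        )
        out = compare_groups(df)
        assert out["method"].iloc[0] == "anova"
        assert (out["method"].iloc[1:] == "anova_sidak").all()
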