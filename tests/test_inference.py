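import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from chasekit.inference import (
    comparison_battery,
    hedges_g,
    holm,
    jzs_ln_bf,
    mixed_anova_2x2,
    paired_t,
    welch_t,
    within_subject_ci,
)


class TestWelchT:
    def test_identical_samples(self):
        t, df, p, ci = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)
        assert ci[0] < 0 < ci[1]

    def test_hand_computed_example(self):
        t, df, p, ci = welch_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247448, abs=1e-6)
        assert df == pytest.approx(4.0)

    def test_matches_scipy(self, rng):
        for _ in range(25):
            x = rng.normal(0, 1, int(rng.integers(5, 40)))
            y = rng.normal(0.3, 2, int(rng.integers(5, 40)))
            t, df, p, _ = welch_t(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert df == pytest.approx(ref.df, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)
            lo, hi = ref.confidence_interval(0.95)
            assert welch_t(x, y)[3] == pytest.approx((lo, hi), rel=1e-10)

    def test_shift_invariance(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 12)
        t1, df1, p1, _ = welch_t(x, y)
        t2, df2, p2, _ = welch_t(x + 5, y + 5)
        assert (t1, df1, p1) == pytest.approx((t2, df2, p2))

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0, 1.0], [1, 2, 3])
        with pytest.raises(ValueError):
            welch_t([1.0], [1, 2, 3])


class TestPairedT:
    def test_hand_computed_example(self):
        t, df, p, ci = paired_t([1, 1, 1, 5])
        assert t == pytest.approx(2.0) and df == 3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_t([0.0, 0.0, 0.0])

    def test_sign_antisymmetry(self, rng):
        d = rng.normal(0.4, 1, 20)
        assert paired_t(-d)[0] == pytest.approx(-paired_t(d)[0])

    def test_matches_scipy(self, rng):
        d = rng.normal(0.2, 1, 15)
        t, df, p, _ = paired_t(d)
        ref = stats.ttest_1samp(d, 0)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)


class TestJzsLnBf:
    def test_null_favoring_at_t0(self):
        assert jzs_ln_bf(0.0, 50, 49) < 0

    def test_monotone_in_t(self):
        vals = [jzs_ln_bf(t, 50, 49) for t in (0, 0.5, 1, 2, 3, 5, 8)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("t", [0.0, 1.0, 2.0, 4.0])
    @pytest.mark.parametrize("n", [10, 50, 200])
    def test_matches_nct_quadrature_oracle(self, t, n):
        # independent route: Cauchy prior integrated as a dense trapezoid
        # over the tan substitution of the noncentral-t likelihood
        df = n - 1
        theta = np.linspace(-np.pi / 2 + 1e-9, np.pi / 2 - 1e-9, 200_001)
        delta = 0.707 * np.tan(theta)
        with np.errstate(all="ignore"):
            f = stats.nct.pdf(t, df, delta * np.sqrt(n)) / np.pi
        f = np.nan_to_num(f)
        oracle = math.log(np.trapezoid(f, theta)) - stats.t.logpdf(t, df)
        mine = jzs_ln_bf(t, n, df)
        assert mine == pytest.approx(oracle, rel=1e-6)

    def test_matches_pingouin_paired(self):
        for t, n in [(0.5, 12), (2.5, 30), (-3.0, 80)]:
            ref = math.log(pg.bayesfactor_ttest(t, n, paired=True, r=0.707))
            assert jzs_ln_bf(t, n, n - 1) == pytest.approx(ref, rel=1e-6)

    def test_matches_pingouin_two_sample(self):
        n1, n2, t = 20, 25, 2.0
        ref = math.log(pg.bayesfactor_ttest(t, n1, n2, paired=False, r=0.707))
        mine = jzs_ln_bf(t, n1 * n2 / (n1 + n2), n1 + n2 - 2)
        assert mine == pytest.approx(ref, rel=1e-6)

    def test_extreme_t_large_df_stable(self):
        # magnitudes the real battery produces must not overflow
        val = jzs_ln_bf(68.5, 1679, 1678)
        assert np.isfinite(val) and val > 1000

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            jzs_ln_bf(1.0, 10, 0.5)
        with pytest.raises(ValueError):
            jzs_ln_bf(1.0, -3, 10)


class TestHedgesG:
    def test_identical_samples_zero(self):
        assert hedges_g([1, 2, 3], [1, 2, 3]) == 0.0

    def test_between_hand_example(self):
        # pooled sd = 1, uncorrected d = -2
        g = hedges_g([1, 2, 3], [3, 4, 5], design="between")
        assert g == pytest.approx(-2.0 * (1 - 3 / (4 * 4 - 1)))

    def test_sign_flips_on_swap(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        assert hedges_g(a, b) == pytest.approx(-hedges_g(b, a))

    def test_between_matches_pingouin(self, rng):
        a, b = rng.normal(0, 1, 14), rng.normal(0.6, 1.4, 19)
        ref = pg.compute_effsize(a, b, eftype="hedges")
        assert hedges_g(a, b, design="between") == pytest.approx(ref, rel=1e-10)

    def test_within_average_standardizer(self):
        a = np.array([3.0, 4.0, 5.0, 6.0])
        b = np.array([1.0, 1.5, 2.0, 2.5])
        # mean diff 2.75, sds sqrt(5/3) and sqrt(5/12); average of sds
        s_av = (math.sqrt(5 / 3) + math.sqrt(5 / 12)) / 2
        expect = 2.75 / s_av * (1 - 3 / (4 * 3 - 1))
        assert hedges_g(a, b, design="within") == pytest.approx(expect)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            hedges_g([1, 1, 1], [2, 2, 2], design="between")


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm([0.04]) == pytest.approx([0.04])

    def test_hand_example(self):
        assert holm([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_all_ones(self):
        assert holm([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_matches_statsmodels(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(2, 12)))
            ref = multipletests(p, method="holm")[1]
            assert holm(p) == pytest.approx(ref, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm([0.5, 1.2])


def _sm_anova_oracle(tab):
    """Independent Type-III split-plot oracle via statsmodels OLS."""
    d = pd.DataFrame(
        {
            "s": (tab["value_loss"] + tab["value_win"]) / math.sqrt(2),
            "w": (tab["value_loss"] - tab["value_win"]) / math.sqrt(2),
            "grp": tab["group"],
        }
    )
    a1 = anova_lm(smf.ols("s ~ C(grp, Sum)", d).fit(), typ=3)
    a2 = anova_lm(smf.ols("w ~ C(grp, Sum)", d).fit(), typ=3)
    N = len(d)
    ss = {
        "group": a1.loc["C(grp, Sum)", "sum_sq"],
        "subj": a1.loc["Residual", "sum_sq"],
        "outcome": a2.loc["Intercept", "sum_sq"],
        "interaction": a2.loc["C(grp, Sum)", "sum_sq"],
        "err": a2.loc["Residual", "sum_sq"],
    }
    out = {}
    for eff, err in (("group", "subj"), ("outcome", "err"), ("interaction", "err")):
        f = ss[eff] / (ss[err] / (N - 2))
        ges = ss[eff] / (ss[eff] + ss["subj"] + ss["err"])
        out[eff] = (f, ges, stats.f.sf(f, 1, N - 2))
    return out


class TestMixedAnova:
    def test_pure_within_shift(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 15)
        tab = pd.DataFrame(
            {
                "group": ["high"] * 15 + ["low"] * 15,
                "value_win": np.r_[base, base],  # identical groups
                "value_loss": np.r_[base, base] + 2.0,
            }
        )
        res = mixed_anova_2x2(tab)
        assert res.outcome.f > 1e10  # exact shift, error ~ 0
        assert res.group.f == pytest.approx(0.0, abs=1e-12)
        assert res.interaction.f == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_unbalanced(self, rng):
        tab = pd.DataFrame(
            {
                "group": ["high"] * 27 + ["low"] * 13,
                "value_loss": rng.normal(1, 0.7, 40),
                "value_win": rng.normal(0.2, 1.1, 40),
            }
        )
        res = mixed_anova_2x2(tab)
        ref = _sm_anova_oracle(tab)
        for eff in ("group", "outcome", "interaction"):
            e = getattr(res, eff)
            assert e.f == pytest.approx(ref[eff][0], abs=1e-8, rel=1e-10)
            assert e.ges == pytest.approx(ref[eff][1], abs=1e-10)
            assert e.p == pytest.approx(ref[eff][2], abs=1e-10)
            assert (e.df_num, e.df_den) == (1, 38)

    def test_matches_pingouin_balanced(self, rng):
        tab = pd.DataFrame(
            {
                "group": ["high"] * 20 + ["low"] * 20,
                "value_loss": rng.normal(1, 0.7, 40),
                "value_win": rng.normal(0.2, 1.1, 40),
            }
        )
        res = mixed_anova_2x2(tab)
        long = tab.reset_index().melt(
            id_vars=["index", "group"], value_vars=["value_loss", "value_win"]
        )
        ref = pg.mixed_anova(
            data=long, dv="value", within="variable", subject="index", between="group"
        ).set_index("Source")
        assert res.group.f == pytest.approx(ref.loc["group", "F"], rel=1e-8)
        assert res.outcome.f == pytest.approx(ref.loc["variable", "F"], rel=1e-8)
        assert res.interaction.f == pytest.approx(ref.loc["Interaction", "F"], rel=1e-8)

    def test_small_group_rejected(self):
        tab = pd.DataFrame(
            {"group": ["high", "high", "low"], "value_loss": [1, 2, 3.0], "value_win": [0, 1, 2.0]}
        )
        with pytest.raises(ValueError):
            mixed_anova_2x2(tab)


class TestWithinSubjectCI:
    def test_perfect_consistency_zero_width(self):
        loss = np.array([1.0, 2.0, 3.0, 4.0])
        win = loss - 0.7
        ci = within_subject_ci(loss, win)
        for cond in ("loss", "win"):
            m, lo, hi = ci[cond]
            assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_subject_offset_invariance(self, rng):
        loss, win = rng.normal(1, 1, 10), rng.normal(0, 1, 10)
        offs = rng.normal(0, 5, 10)
        c1 = within_subject_ci(loss, win)
        c2 = within_subject_ci(loss + offs, win + offs)
        for cond in ("loss", "win"):
            assert c1[cond][2] - c1[cond][1] == pytest.approx(
                c2[cond][2] - c2[cond][1], abs=1e-10
            )

    def test_closed_form_half_width(self, rng):
        # with 2 conditions and the Morey correction, the half-width equals
        # t_{.975,n-1} * sd(diff) / sqrt(2 n)
        loss, win = rng.normal(1, 1, 14), rng.normal(0, 2, 14)
        ci = within_subject_ci(loss, win)
        n = 14
        expect = stats.t.ppf(0.975, n - 1) * np.std(loss - win, ddof=1) / math.sqrt(2 * n)
        for cond in ("loss", "win"):
            assert ci[cond][0] - ci[cond][1] == pytest.approx(expect, rel=1e-12)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            within_subject_ci([1.0], [2.0])


@pytest.fixture(scope="module")
def facet_table():
    rng = np.random.default_rng(77)
    n_hi, n_lo = 60, 40
    return pd.DataFrame(
        {
            "group": ["high"] * n_hi + ["low"] * n_lo,
            "value_loss": np.r_[rng.normal(1.2, 0.3, n_hi), rng.normal(1.2, 0.3, n_lo)],
            "value_win": np.r_[rng.normal(0.4, 0.5, n_hi), rng.normal(0.3, 0.5, n_lo)],
        }
    )


class TestComparisonBattery:
    def test_row_structure(self, facet_table):
        b = comparison_battery(facet_table, "value_loss", "value_win", facet="stop")
        assert len(b.comparisons) == 5
        assert list(b.comparisons["comparison"])[:2] == [
            "High-Loss vs. High-Win",
            "Low-Loss vs. Low-Win",
        ]
        assert not b.empty and b.anova is not None

    def test_within_rows_detect_built_in_effect(self, facet_table):
        b = comparison_battery(facet_table, "value_loss", "value_win")
        c = b.comparisons.set_index("comparison")
        for row in ("High-Loss vs. High-Win", "Low-Loss vs. Low-Win"):
            assert c.loc[row, "p_holm"] < 0.05
            assert c.loc[row, "diff"] > 0
            assert c.loc[row, "ln_bf"] > 3

    def test_holm_monotone_in_p_raw(self, facet_table):
        b = comparison_battery(facet_table, "value_loss", "value_win")
        c = b.comparisons.sort_values("p_raw")
        assert (np.diff(c["p_holm"]) >= -1e-15).all()
        assert (c["p_holm"] >= c["p_raw"] - 1e-15).all()

    def test_ci_brackets_diff(self, facet_table):
        b = comparison_battery(facet_table, "value_loss", "value_win")
        c = b.comparisons
        assert ((c["ci_low"] <= c["diff"]) & (c["diff"] <= c["ci_high"])).all()

    def test_empty_analysis_set(self):
        empty = pd.DataFrame({"group": [], "value_loss": [], "value_win": []})
        b = comparison_battery(empty, "value_loss", "value_win")
        assert b.empty and len(b.comparisons) == 0 and b.anova is None

    def test_null_between_group_lnbf_mostly_negative(self):
        rng = np.random.default_rng(5)
        neg = 0
        for _ in range(20):
            tab = pd.DataFrame(
                {
                    "group": ["high"] * 50 + ["low"] * 50,
                    "value_loss": rng.normal(1, 0.5, 100),
                    "value_win": rng.normal(0, 0.5, 100),
                }
            )
            b = comparison_battery(tab, "value_loss", "value_win")
            c = b.comparisons.set_index("comparison")
            neg += c.loc["High-Loss vs. Low-Loss", "ln_bf"] < 0
        assert neg >= 15  # identical groups: null favored in most replicates
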