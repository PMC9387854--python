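"""Statistical battery for the facet tables.

Implements Welch and paired t-tests with 95% CIs, Holm step-down p
adjustment, Hedges' g (pooled for between-group contrasts, the
average-standardiser variant for paired contrasts), the default-prior
(Cauchy scale 0.707) Bayes-factor t-test on the natural-log scale, a 2x2
mixed ANOVA (one between, one within factor, Type-III sums of squares,
generalized eta squared) and Morey-corrected within-subject condition
CIs.  ``comparison_battery`` assembles them into the five standard
pairwise contrasts plus the ANOVA for each facet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "TestResult",
    "AnovaResult",
    "FacetBattery",
    "welch_t",
    "paired_t",
    "jzs_ln_bf",
    "hedges_g",
    "holm",
    "mixed_anova_2x2",
    "within_subject_ci",
    "comparison_battery",
]


@dataclass
class TestResult:
    """One pairwise comparison row (the Tables 4-6 style schema)."""

    comparison: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    diff: float
    ci_low: float
    ci_high: float
    df: float
    t: float
    p_raw: float
    p_holm: float
    ln_bf: float
    g: float


@dataclass
class AnovaEffect:
    effect: str
    df_num: int
    df_den: int
    mse: float
    f: float
    ges: float
    p: float


@dataclass
class AnovaResult:
    """2x2 mixed ANOVA: between-group, within-outcome and interaction effects."""

    group: AnovaEffect
    outcome: AnovaEffect
    interaction: AnovaEffect

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(e) for e in (self.group, self.outcome, self.interaction)]
        return pd.DataFrame(rows)


def _check_sample(x: np.ndarray, name: str, min_n: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < min_n:
        raise ValueError(f"sample {name} needs at least {min_n} observations")
    if np.var(x, ddof=1) <= 0:
        raise ValueError(f"sample {name} has zero variance")
    return x


def welch_t(x, y, level: float = 0.95) -> tuple[float, float, float, tuple[float, float]]:
    """Unequal-variance two-sample t-test.

    Returns ``(t, df, p, (ci_low, ci_high))`` for the difference of means
    ``mean(x) - mean(y)`` with Welch-Satterthwaite degrees of freedom.
    """
    x = _check_sample(x, "x")
    y = _check_sample(y, "y")
    n1, n2 = len(x), len(y)
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (np.mean(x) - np.mean(y)) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    crit = stats.t.ppf(0.5 + level / 2, df)
    diff = np.mean(x) - np.mean(y)
    half = crit * math.sqrt(se2)
    return float(t), float(df), float(p), (float(diff - half), float(diff + half))


def paired_t(diffs, level: float = 0.95) -> tuple[float, float, float, tuple[float, float]]:
    """One-sample t-test on difference scores; df = n - 1."""
    d = _check_sample(diffs, "diffs")
    n = len(d)
    m, s = np.mean(d), np.std(d, ddof=1)
    se = s / math.sqrt(n)
    t = m / se
    df = n - 1
    p = 2 * stats.t.sf(abs(t), df)
    crit = stats.t.ppf(0.5 + level / 2, df)
    return float(t), float(df), float(p), (float(m - crit * se), float(m + crit * se))


def jzs_ln_bf(t: float, n_eff: float, df: float, r: float = 0.707) -> float:
    """Natural log of the default-prior Bayes factor for a t statistic.

    BF10 = integral of the noncentral-t likelihood of *t* over a Cauchy
    prior (scale *r*) on the standardised effect size, divided by the
    central-t likelihood.  For a paired/one-sample design ``n_eff = n``
    and ``df = n - 1``; for two independent samples
    ``n_eff = n1*n2/(n1+n2)`` and ``df = n1 + n2 - 2``.
    """
    if df < 1:
        raise ValueError("df must be at least 1")
    if n_eff <= 0 or r <= 0:
        raise ValueError("n_eff and r must be positive")
    # The Cauchy(0, r) prior on the effect size is the scale mixture
    # delta | g ~ N(0, g r^2), g ~ InverseGamma(1/2, 1/2).  Marginalising
    # the noncentral-t likelihood over delta in closed form leaves a 1-D
    # integral over g, evaluated here in log space on the substitution
    # g = exp(u) (the t-density constants cancel against the null).
    t2, v = t * t, float(df)

    def log_num_integrand(u: float) -> float:
        a = 1.0 + n_eff * math.exp(u) * r * r
        return (
            -0.5 * math.log(a)
            - 0.5 * (v + 1.0) * math.log1p(t2 / (a * v))
            - 0.5 * math.log(2.0 * math.pi)
            - 0.5 * u
            - 0.5 * math.exp(-u)
        )

    grid = np.linspace(-25.0, 25.0, 201)
    shift = max(log_num_integrand(u) for u in grid)
    if not np.isfinite(shift):
        raise ArithmeticError("Bayes factor integrand is degenerate")
    val, err = integrate.quad(
        lambda u: math.exp(log_num_integrand(u) - shift), -50.0, 50.0, limit=400
    )
    if not np.isfinite(val) or val <= 0 or err > 1e-6 * val + 1e-12:
        raise ArithmeticError(
            f"Bayes factor quadrature did not converge (value={val}, abserr={err})"
        )
    log_num = shift + math.log(val)
    log_den = -0.5 * (v + 1.0) * math.log1p(t2 / v)
    return float(log_num - log_den)


def _small_sample_correction(df: float) -> float:
    # standard approximation of the exact gamma-ratio bias correction
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def hedges_g(a, b, design: str = "between") -> float:
    """Bias-corrected standardised mean difference.

    ``between``: pooled-sd standardiser, correction with df = n1+n2-2.
    ``within`` (the "average g"): mean paired difference divided by the
    average of the two condition sds, correction with df = n-1.
    """
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    if design == "between":
        n1, n2 = len(a), len(b)
        df = n1 + n2 - 2
        sp = math.sqrt(((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / df)
        d = (np.mean(a) - np.mean(b)) / sp
        return float(d * _small_sample_correction(df))
    if design == "within":
        if len(a) != len(b):
            raise ValueError("within design needs paired samples of equal length")
        s_av = (np.std(a, ddof=1) + np.std(b, ddof=1)) / 2
        if s_av == 0:
            raise ValueError("zero variance in both conditions")
        d = (np.mean(a) - np.mean(b)) / s_av
        return float(d * _small_sample_correction(len(a) - 1))
    raise ValueError(f"unknown design {design!r}")


def holm(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")  # ties keep original index order
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def mixed_anova_2x2(
    table: pd.DataFrame,
    group_col: str = "group",
    loss_col: str = "value_loss",
    win_col: str = "value_win",
) -> AnovaResult:
    """2x2 mixed ANOVA: between factor *group* (2 levels), within factor
    outcome (loss vs win), one row per subject.

    Uses Type-III sums of squares (unweighted cell means, relevant for
    unbalanced groups).  The generalized eta squared counts both error
    strata (between-subject and within-subject) in its denominator.  All
    three effects have df (1, N-2).
    """
    levels = sorted(table[group_col].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    y_loss = [table.loc[table[group_col] == lv, loss_col].to_numpy(dtype=float) for lv in levels]
    y_win = [table.loc[table[group_col] == lv, win_col].to_numpy(dtype=float) for lv in levels]
    n = [len(v) for v in y_loss]
    if min(n) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if any(np.isnan(v).any() for v in y_loss + y_win):
        raise ValueError("complete within-subject pairs required (NaN found)")
    N = sum(n)
    inv = 1.0 / n[0] + 1.0 / n[1]
    # orthonormal within-subject contrasts: sum and difference
    s = [(l + w) / math.sqrt(2) for l, w in zip(y_loss, y_win)]
    w = [(l - w) / math.sqrt(2) for l, w in zip(y_loss, y_win)]
    s_bar = [v.mean() for v in s]
    w_bar = [v.mean() for v in w]
    ss_group = (s_bar[0] - s_bar[1]) ** 2 / inv
    ss_subj = sum(((v - m) ** 2).sum() for v, m in zip(s, s_bar))
    ss_outcome = ((w_bar[0] + w_bar[1]) / 2) ** 2 / (inv / 4)
    ss_inter = (w_bar[0] - w_bar[1]) ** 2 / inv
    ss_err_w = sum(((v - m) ** 2).sum() for v, m in zip(w, w_bar))
    df_den = N - 2
    mse_b = ss_subj / df_den
    mse_w = ss_err_w / df_den
    ss_error_total = ss_subj + ss_err_w

    def effect(name: str, ss: float, mse: float) -> AnovaEffect:
        f = ss / mse
        return AnovaEffect(
            effect=name,
            df_num=1,
            df_den=df_den,
            mse=float(mse),
            f=float(f),
            ges=float(ss / (ss + ss_error_total)),
            p=float(stats.f.sf(f, 1, df_den)),
        )

    return AnovaResult(
        group=effect("group", ss_group, mse_b),
        outcome=effect("outcome", ss_outcome, mse_w),
        interaction=effect("interaction", ss_inter, mse_w),
    )


def within_subject_ci(
    loss, win, level: float = 0.95
) -> dict[str, tuple[float, float, float]]:
    """Within-subject condition CIs (subject-centred, bias-corrected).

    Each subject's two values are centred on the subject mean and
    re-centred at the grand mean; the per-condition variance of these
    centred values is inflated by J/(J-1) = 2 before forming t-based CIs.
    Returns ``{condition: (mean, ci_low, ci_high)}``.
    """
    loss = np.asarray(loss, dtype=float)
    win = np.asarray(win, dtype=float)
    if loss.shape != win.shape or loss.ndim != 1:
        raise ValueError("loss and win must be equal-length vectors")
    n = len(loss)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    subj_mean = (loss + win) / 2
    grand = (loss.mean() + win.mean()) / 2
    out = {}
    crit = stats.t.ppf(0.5 + level / 2, n - 1)
    for name, vals in (("loss", loss), ("win", win)):
        centred = vals - subj_mean + grand
        var = np.var(centred, ddof=1) * 2.0  # J/(J-1) with J=2
        half = crit * math.sqrt(var / n)
        m = vals.mean()
        out[name] = (float(m), float(m - half), float(m + half))
    return out


@dataclass
class FacetBattery:
    """ANOVA plus the five pairwise comparisons for one facet."""

    facet: str
    anova: AnovaResult | None
    comparisons: pd.DataFrame  # one TestResult row per comparison
    within_ci: dict | None
    empty: bool = False


def _describe(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1))


def comparison_battery(
    table: pd.DataFrame,
    value_loss: str,
    value_win: str,
    facet: str = "",
    group_col: str = "group",
    bf_r: float = 0.707,
    level: float = 0.95,
) -> FacetBattery:
    """The five standard contrasts plus the mixed ANOVA for one facet table.

    *table* must contain one row per included player with the group label
    and the two per-outcome values.  Holm correction is applied within
    the 5-comparison family of this facet.
    """
    df = table.dropna(subset=[value_loss, value_win])
    hi = df[df[group_col] == "high"]
    lo = df[df[group_col] == "low"]
    if len(hi) < 2 or len(lo) < 2:
        return FacetBattery(
            facet=facet,
            anova=None,
            comparisons=pd.DataFrame(columns=[f.name for f in fields(TestResult)]),
            within_ci=None,
            empty=True,
        )
    hi_loss = hi[value_loss].to_numpy(dtype=float)
    hi_win = hi[value_win].to_numpy(dtype=float)
    lo_loss = lo[value_loss].to_numpy(dtype=float)
    lo_win = lo[value_win].to_numpy(dtype=float)
    hi_diff = hi_loss - hi_win
    lo_diff = lo_loss - lo_win

    rows: list[TestResult] = []

    def add_paired(name: str, a: np.ndarray, b: np.ndarray) -> None:
        d = a - b
        t, dfree, p, ci = paired_t(d)
        n = len(d)
        rows.append(
            TestResult(
                comparison=name,
                mean_a=_describe(a)[0],
                sd_a=_describe(a)[1],
                mean_b=_describe(b)[0],
                sd_b=_describe(b)[1],
                diff=float(np.mean(d)),
                ci_low=ci[0],
                ci_high=ci[1],
                df=dfree,
                t=t,
                p_raw=p,
                p_holm=np.nan,
                ln_bf=jzs_ln_bf(t, n, n - 1, r=bf_r),
                g=hedges_g(a, b, design="within"),
            )
        )

    def add_welch(name: str, a: np.ndarray, b: np.ndarray) -> None:
        t, dfree, p, ci = welch_t(a, b)
        n1, n2 = len(a), len(b)
        rows.append(
            TestResult(
                comparison=name,
                mean_a=_describe(a)[0],
                sd_a=_describe(a)[1],
                mean_b=_describe(b)[0],
                sd_b=_describe(b)[1],
                diff=float(np.mean(a) - np.mean(b)),
                ci_low=ci[0],
                ci_high=ci[1],
                df=dfree,
                t=t,
                p_raw=p,
                p_holm=np.nan,
                ln_bf=jzs_ln_bf(t, n1 * n2 / (n1 + n2), n1 + n2 - 2, r=bf_r),
                g=hedges_g(a, b, design="between"),
            )
        )

    add_paired("High-Loss vs. High-Win", hi_loss, hi_win)
    add_paired("Low-Loss vs. Low-Win", lo_loss, lo_win)
    add_welch("High-Loss vs. Low-Loss", hi_loss, lo_loss)
    add_welch("High-Win vs. Low-Win", hi_win, lo_win)
    add_welch("(High-Loss - High-Win) vs. (Low-Loss - Low-Win)", hi_diff, lo_diff)

    comparisons = pd.DataFrame([vars(r) for r in rows])
    comparisons["p_holm"] = holm(comparisons["p_raw"].to_numpy())

    anova = mixed_anova_2x2(
        df.rename(columns={value_loss: "value_loss", value_win: "value_win"}),
        group_col=group_col,
    )
    ci = within_subject_ci(
        np.concatenate([hi_loss, lo_loss]), np.concatenate([hi_win, lo_win]), level=level
    )
    return FacetBattery(facet=facet, anova=anova, comparisons=comparisons, within_ci=ci)
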