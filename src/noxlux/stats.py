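"""Comparison statistics: fixed-effects ANOVA, Bonferroni-corrected
t-tests and ordinary least-squares regression.

Conventions: unbalanced designs use Type-II sums of squares; unpaired
t-tests are Welch (unequal variances) by default with pooled-variance
available by flag; the Bonferroni family size ``m`` is declared by the
caller's comparison plan, and adjusted p = min(1, m * raw p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "ANOVATable",
    "GroupComparison",
    "RegressionResult",
    "anova",
    "anova_oneway_summary",
    "bonferroni_ttests",
    "fit_delay_regression",
]


@dataclass
class ANOVATable:
    """Fixed-effects ANOVA results, one row per model term."""

    table: pd.DataFrame  # columns: sum_sq, df, F, p
    factors: list[str]
    ss_type: int = 2

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def f_value(self, term: str) -> float:
        return float(self.table.loc[term, "F"])


@dataclass(frozen=True)
class GroupComparison:
    """One planned pairwise comparison with its Bonferroni-adjusted p."""

    group_a: str
    group_b: str
    paired: bool
    t: float
    df: float
    p_raw: float
    p_adjusted: float
    mean_difference: float


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least-squares line fit with standard errors."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    n: int


def anova(
    data: pd.DataFrame,
    response: str,
    factors: list[str],
    interactions: bool = False,
    ss_type: int = 2,
) -> ANOVATable:
    """Fixed-effects ANOVA with all main effects (interactions optional).

    ``data`` holds one observation per row with categorical factor
    columns.  Each factor needs >= 2 observed levels and the residual
    at least 1 degree of freedom.  Type-II sums of squares are the
    default so unbalanced designs are handled symmetrically.
    """
    if not factors:
        raise ValueError("need at least one factor")
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    y = data[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("all observations identical: F is undefined")
    terms = [f"C({f})" for f in factors]
    rhs = " * ".join(terms) if interactions else " + ".join(terms)
    model = smf.ols(f"{response} ~ {rhs}", data=data).fit()
    if model.df_resid < 1:
        raise ValueError("no residual degrees of freedom (singular or saturated design)")
    raw = anova_lm(model, typ=ss_type)
    raw = raw.rename(columns={"PR(>F)": "p"})
    # strip the C(...) wrappers for readable term names
    raw.index = [t.replace("C(", "").replace(")", "") for t in raw.index]
    table = raw[["sum_sq", "df", "F", "p"]]
    return ANOVATable(table=table, factors=list(factors), ss_type=ss_type)


def anova_oneway_summary(
    means: np.ndarray, sds: np.ndarray, ns: np.ndarray
) -> tuple[float, float]:
    """One-way ANOVA from per-group summary statistics (mean, SD, n).

    Returns (F, p).  Useful when only printed group summaries are
    available rather than raw observations.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, float)
    k = means.size
    if k < 2 or np.any(ns < 2):
        raise ValueError("need >= 2 groups with n >= 2 each")
    n_tot = ns.sum()
    grand = (ns * means).sum() / n_tot
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    df_b, df_w = k - 1, n_tot - k
    if ss_within == 0:
        raise ValueError("zero within-group variance: F is undefined")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


def bonferroni_ttests(
    groups: dict[str, np.ndarray],
    plan: list[tuple[str, str]],
    paired: bool | list[bool] = False,
    welch: bool = True,
    m: int | None = None,
) -> list[GroupComparison]:
    """Planned pairwise t-tests with Bonferroni adjustment.

    ``plan`` lists the (a, b) comparisons; ``paired`` is one flag or a
    per-comparison list; ``m`` is the family size for the correction
    (defaults to the number of planned comparisons).  Unpaired tests are
    Welch unless ``welch=False`` requests the pooled-variance Student
    form; paired tests require matched equal-length vectors.
    """
    if not plan:
        return []
    flags = [paired] * len(plan) if isinstance(paired, bool) else list(paired)
    if len(flags) != len(plan):
        raise ValueError("paired flags must match the comparison plan")
    m_eff = len(plan) if m is None else int(m)
    if m_eff < 1:
        raise ValueError("family size m must be >= 1")
    out = []
    for (a, b), is_paired in zip(plan, flags):
        x = np.asarray(groups[a], float)
        y = np.asarray(groups[b], float)
        if x.size < 2 or y.size < 2:
            raise ValueError(f"comparison {a} vs {b}: need n >= 2 per group")
        if is_paired:
            if x.size != y.size:
                raise ValueError(f"paired comparison {a} vs {b}: unequal lengths")
            res = sps.ttest_rel(x, y)
            df = x.size - 1
        else:
            res = sps.ttest_ind(x, y, equal_var=not welch)
            df = float(res.df)
        t = float(res.statistic)
        p = float(res.pvalue)
        if not np.isfinite(t):  # identical constant groups
            t, p = 0.0, 1.0
        out.append(
            GroupComparison(
                group_a=a,
                group_b=b,
                paired=is_paired,
                t=t,
                df=float(df),
                p_raw=p,
                p_adjusted=min(1.0, m_eff * p),
                mean_difference=float(x.mean() - y.mean()),
            )
        )
    return out


def fit_delay_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares y = a*x + b with standard errors and R².

    Intended for the waking-peak-delay vs exposure-index fit, but fully
    generic.  Requires n >= 3 for standard errors (n = 2 reproduces the
    two points exactly with R² = 1 and undefined SEs).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need matched x/y with n >= 2")
    if np.ptp(x) == 0:
        raise ValueError("constant x: slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    b, a = model.params
    if x.size == 2:
        se_b, se_a = float("nan"), float("nan")
        r2 = 1.0
    else:
        se_b, se_a = model.bse
        r2 = float(model.rsquared) if np.ptp(y) > 0 else 0.0
    if np.ptp(y) == 0:
        r2 = 0.0
    return RegressionResult(
        slope=float(a),
        slope_se=float(se_a),
        intercept=float(b),
        intercept_se=float(se_b),
        r_squared=float(r2),
        n=int(x.size),
    )
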