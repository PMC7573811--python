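"""Rest-activity analysis: rebinning, circadian periodogram, DFA.

The two estimators operate on :class:`~noxlux.core.ActivityTrace` objects:

* :func:`periodogram` — a folded variance-explained (eta-squared)
  periodogram over a grid of candidate periods, with a chi-square null
  threshold.  The peak period estimates the circadian period and the
  statistic at the peak is the rhythm strength.
* :func:`dfa` — detrended fluctuation analysis (first order): integrate
  the mean-centred counts to a profile, split into non-overlapping
  windows of size *n*, linearly detrend each window, and average the
  RMS residual into a fluctuation value F(n).  The scaling exponent
  alpha is the slope of log10 F(n) vs log10 n over the 3–8 h circadian
  range; alpha near 1 is the signature of healthy scale-invariant
  rest-activity control, alpha near 0.5 of uncorrelated noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ActivityTrace

__all__ = ["PeriodogramResult", "DFAResult", "bin_activity", "periodogram", "dfa"]


@dataclass
class PeriodogramResult:
    """Folded-periodogram output over a period grid."""

    periods_h: np.ndarray
    statistic: np.ndarray  # eta-squared (variance explained) per period
    threshold: np.ndarray  # chi-square null significance level per period
    peak_period_h: float
    strength: float  # statistic at the peak period

    @property
    def significant(self) -> bool:
        """Whether the peak exceeds its null threshold."""
        i = int(np.argmax(self.statistic))
        return bool(self.statistic[i] > self.threshold[i])


@dataclass
class DFAResult:
    """Fluctuation function and fitted scaling exponent."""

    window_sizes: np.ndarray  # bins
    window_hours: np.ndarray
    fluctuations: np.ndarray  # F(n) per window size
    n_windows: np.ndarray  # number of non-overlapping windows per size
    in_fit_range: np.ndarray  # bool mask of sizes used for the alpha fit
    alpha: float
    intercept: float
    fit_r2: float
    fit_range_h: tuple[float, float]


def bin_activity(trace: ActivityTrace, target_bin_seconds: float) -> ActivityTrace:
    """Re-bin counts to a coarser grid; total counts are conserved exactly.

    ``target_bin_seconds`` must be an integer multiple of the source bin.
    """
    ratio = target_bin_seconds / trace.bin_seconds
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"target bin {target_bin_seconds}s is not an integer multiple "
            f"of source bin {trace.bin_seconds}s"
        )
    k = int(round(ratio))
    if k == 1:
        return trace.with_counts(trace.counts.copy())
    n = (trace.n_bins // k) * k
    if n == 0:
        raise ValueError("trace shorter than one target bin")
    if n < trace.n_bins:
        warnings.warn(
            f"dropping {trace.n_bins - n} trailing source bins that do not fill a target bin",
            stacklevel=2,
        )
    summed = trace.counts[:n].reshape(-1, k).sum(axis=1)
    return trace.with_counts(summed, bin_seconds=float(target_bin_seconds))


def periodogram(
    trace: ActivityTrace,
    period_grid_h: np.ndarray | None = None,
    alpha_level: float = 0.05,
    familywise: bool = True,
    n_columns: int = 288,
) -> PeriodogramResult:
    """Variance-explained folded periodogram with a chi-square null.

    For each candidate period P the trace is folded at P into
    ``n_columns`` equal phase columns (288 by default, i.e. 5-min
    phase resolution at 24 h) and the statistic is the fraction of
    total variance explained by the folded mean waveform (eta-squared).
    A fixed column count keeps the white-noise expectation of the
    statistic identical across the grid, so the argmax is unbiased in
    period; folding phase is computed continuously, so non-integer
    periods (in bins) need no special casing.

    Under the white-noise null, N*eta2 is approximately chi-square with
    ``n_columns - 1`` degrees of freedom, which yields the per-period
    significance threshold; with ``familywise`` the level is
    Bonferroni-divided by the grid size so the *peak* can be compared
    against its threshold.  The default grid spans 20–28 h in 0.05-h
    steps.
    """
    if period_grid_h is None:
        period_grid_h = np.arange(20.0, 28.0 + 1e-9, 0.05)
    period_grid_h = np.asarray(period_grid_h, dtype=float)
    if period_grid_h.size == 0:
        raise ValueError("empty period grid")

    x = trace.counts
    bins_per_hour = 3600.0 / trace.bin_seconds
    max_p_bins = period_grid_h.max() * bins_per_hour
    if x.size < 2 * max_p_bins:
        raise ValueError(
            f"trace ({trace.duration_h:.1f} h) shorter than two cycles of the "
            f"longest tested period ({period_grid_h.max():.2f} h)"
        )
    if x.size < 10 * max_p_bins:
        warnings.warn(
            "trace shorter than 10 cycles of the longest tested period; "
            "periodogram estimates may be unstable",
            stacklevel=2,
        )

    level = alpha_level / period_grid_h.size if familywise else alpha_level
    n = x.size
    total_var = x.var()
    grand = x.mean()
    idx = np.arange(n, dtype=float)
    stat = np.empty(period_grid_h.size)
    thresh = np.empty(period_grid_h.size)
    for i, p_h in enumerate(period_grid_h):
        p_bins = p_h * bins_per_hour
        cols = min(n_columns, int(p_bins))
        if cols < 2:
            raise ValueError(f"period {p_h} h folds into fewer than 2 columns")
        col = np.floor((idx / p_bins % 1.0) * cols).astype(int)
        if total_var == 0:
            stat[i] = 0.0
            thresh[i] = np.inf
            continue
        counts = np.bincount(col, minlength=cols).astype(float)
        sums = np.bincount(col, weights=x, minlength=cols)
        means = sums / counts
        ss_between = (counts * (means - grand) ** 2).sum()
        stat[i] = ss_between / (n * total_var)
        thresh[i] = stats.chi2.ppf(1.0 - level, cols - 1) / n

    peak_i = int(np.argmax(stat))
    return PeriodogramResult(
        periods_h=period_grid_h,
        statistic=stat,
        threshold=thresh,
        peak_period_h=float(period_grid_h[peak_i]),
        strength=float(stat[peak_i]),
    )


def _fluctuation(profile: np.ndarray, n: int) -> float:
    """RMS residual of per-window linear detrends (vectorised DFA-1)."""
    m = profile.size // n
    seg = profile[: m * n].reshape(m, n)
    t = np.arange(n, dtype=float)
    t -= t.mean()
    slope = seg @ t / (t @ t)
    resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * t
    return float(np.sqrt(np.mean(resid**2)))


def _window_sizes(
    n_bins: int, bins_per_hour: float, fit_range_h: tuple[float, float], n_fit_sizes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced window sizes in the fit range plus diagnostic sizes outside."""
    lo = int(round(fit_range_h[0] * bins_per_hour))
    hi = int(round(fit_range_h[1] * bins_per_hour))
    lo = max(lo, 4)  # a linear detrend needs a few points of headroom
    fit_sizes = np.unique(np.round(np.geomspace(lo, hi, n_fit_sizes)).astype(int))
    # diagnostic sizes: half a decade below and above the fit range
    below = np.unique(np.round(np.geomspace(max(4, lo // 3), lo, 5)).astype(int))[:-1]
    above = np.unique(np.round(np.geomspace(hi, hi * 3, 5)).astype(int))[1:]
    above = above[above <= n_bins // 4]  # keep >= 4 windows everywhere
    sizes = np.unique(np.concatenate([below, fit_sizes, above]))
    in_fit = (sizes >= lo) & (sizes <= hi)
    return sizes, in_fit


def dfa(
    trace: ActivityTrace,
    fit_range_h: tuple[float, float] = (3.0, 8.0),
    n_fit_sizes: int = 16,
) -> DFAResult:
    """First-order detrended fluctuation analysis of an activity trace.

    Returns F(n) over log-spaced window sizes and the scaling exponent
    alpha fitted by ordinary least squares on log10 F vs log10 n
    restricted to ``fit_range_h`` (default 3–8 h, the circadian range
    that remains statistically reliable for ~15-day recordings).
    """
    lo_h, hi_h = fit_range_h
    if not (0 < lo_h < hi_h):
        raise ValueError("fit range must satisfy 0 < low < high")
    x = trace.counts
    if np.ptp(x) == 0:
        raise ValueError("constant input: fluctuation function is identically zero")
    bins_per_hour = 3600.0 / trace.bin_seconds
    largest = int(round(hi_h * bins_per_hour))
    if x.size < 4 * largest:
        raise ValueError(
            f"trace ({trace.duration_h:.1f} h) too short: the largest fit window "
            f"({hi_h} h) needs at least 4 non-overlapping repetitions"
        )
    if x.size < 10 * largest:
        warnings.warn(
            f"fewer than 10 repetitions of the largest ({hi_h} h) window; "
            "alpha estimates at the top of the fit range are noisy",
            stacklevel=2,
        )

    sizes, in_fit = _window_sizes(x.size, bins_per_hour, (lo_h, hi_h), n_fit_sizes)
    profile = np.cumsum(x - x.mean())
    fluct = np.array([_fluctuation(profile, int(n)) for n in sizes])
    n_windows = x.size // sizes
    if np.any(fluct[in_fit] <= 0):
        raise ValueError("zero fluctuation inside the fit range (degenerate input)")

    logn = np.log10(sizes[in_fit].astype(float))
    logf = np.log10(fluct[in_fit])
    fit = stats.linregress(logn, logf)
    return DFAResult(
        window_sizes=sizes,
        window_hours=sizes / bins_per_hour,
        fluctuations=fluct,
        n_windows=n_windows,
        in_fit_range=in_fit,
        alpha=float(fit.slope),
        intercept=float(fit.intercept),
        fit_r2=float(fit.rvalue**2),
        fit_range_h=(float(lo_h), float(hi_h)),
    )
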