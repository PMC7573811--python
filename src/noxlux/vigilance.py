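"""Rule-based vigilance-state scoring and timecourse aggregation.

The scorer classifies each 4-s epoch into WAKE / NREM / REM from the
integrated EMG value and the EEG theta/delta power ratio with a rule
cascade: high EMG → WAKE; otherwise a theta-dominant spectrum → REM;
otherwise NREM.  Thresholds are set per recording from bimodal splits
(Otsu's criterion on log values), followed by 3-epoch majority
smoothing.  The rule set is this package's own construction; its
accuracy is defined against simulated ground truth, not against human
visual scoring.

Aggregation helpers express states as percentages of recording time in
ZT-aligned clock bins (2/6/12/24 h), locate the waking peak in the
dark/dim phase, compute day–night amplitudes, and lay recovery-day vs
baseline-day timecourses side by side for paired comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import NREM, REM, STATE_LABELS, WAKE, Hypnogram
from .spectral import DELTA, THETA, EpochSpectra, band_power

__all__ = [
    "StateTimecourse",
    "PeakResult",
    "AmplitudeResult",
    "score_epochs",
    "state_percent_timecourse",
    "waking_peak",
    "daily_amplitude",
    "compare_recovery_to_baseline",
]


@dataclass
class StateTimecourse:
    """Per-bin state percentages of recording time.

    ``percent[b, s]`` is the percentage of epochs in clock bin ``b``
    scored as state ``s`` (columns ordered WAKE, NREM, REM); rows sum
    to 100.  ``interval_labels`` tag each bin L1/D1/L2/D2-style: light
    (L) or dark/dim (D) phase, numbered by recording day.
    """

    bin_start_zt_h: np.ndarray
    percent: np.ndarray  # (n_bins, 3)
    counts: np.ndarray  # (n_bins, 3) epoch counts
    n_artifact: np.ndarray  # artifact epochs per bin (informational)
    bin_hours: float
    interval_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        sums = self.percent.sum(axis=1)
        if np.any(np.abs(sums - 100.0) > 1e-9):
            raise ValueError("per-bin state percentages must sum to 100")

    @property
    def n_bins(self) -> int:
        return int(self.percent.shape[0])

    def state_percent(self, state: int) -> np.ndarray:
        return self.percent[:, state]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin_start_zt": self.bin_start_zt_h,
                "WAKE": self.percent[:, WAKE],
                "NREM": self.percent[:, NREM],
                "REM": self.percent[:, REM],
                "n_artifact": self.n_artifact,
            }
        )
        if self.interval_labels:
            df["interval"] = self.interval_labels
        return df


@dataclass(frozen=True)
class PeakResult:
    """Location of a state's maximal 2-h bin inside a search interval."""

    peak_zt_h: float  # bin midpoint
    peak_value: float  # percent
    search_interval: tuple[float, float]


@dataclass(frozen=True)
class AmplitudeResult:
    """Day–night amplitude per state: dark mean % − light mean %."""

    wake: float
    nrem: float
    rem: float

    def as_dict(self) -> dict[str, float]:
        return {"WAKE": self.wake, "NREM": self.nrem, "REM": self.rem}


def _otsu_split(values: np.ndarray, n_bins: int = 256) -> tuple[float, float]:
    """Otsu threshold on a 1-D sample; returns (threshold, separation).

    ``separation`` is the between-class mean difference in pooled-SD
    units — a crude bimodality score used to decide whether the split
    is trustworthy.
    """
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return lo, 0.0
    hist, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    mean_all = cum_m[-1] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        w0 = cum_w / total
        w1 = 1.0 - w0
        mu0 = cum_m / cum_w
        mu1 = (cum_m[-1] - cum_m) / (total - cum_w)
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -1.0
    k = int(np.argmax(between[:-1]))
    thr = centers[k]
    sd = values.std()
    sep = abs(mu1[k] - mu0[k]) / sd if sd > 0 else 0.0
    _ = mean_all
    return float(thr), float(sep)


def _threshold(values: np.ndarray, fallback_quantile: float, what: str, min_sep: float = 1.0) -> float:
    thr, sep = _otsu_split(values)
    if sep < min_sep:
        warnings.warn(
            f"{what}: distribution not clearly bimodal (separation {sep:.2f}); "
            f"falling back to the {fallback_quantile:.0%} quantile",
            stacklevel=3,
        )
        return float(np.quantile(values, fallback_quantile))
    return thr


def _majority_smooth(states: np.ndarray) -> np.ndarray:
    """3-epoch majority vote; the centre epoch wins ties.  Ends unchanged."""
    out = states.copy()
    if states.size < 3:
        return out
    prev, cur, nxt = states[:-2], states[1:-1], states[2:]
    neighbours_agree = prev == nxt
    out[1:-1] = np.where(neighbours_agree & (prev != cur), prev, cur)
    return out


def score_epochs(
    spectra: EpochSpectra,
    smooth: bool = True,
    emg_fallback_quantile: float = 0.5,
    ratio_fallback_quantile: float = 0.85,
) -> Hypnogram:
    """Score every epoch WAKE / NREM / REM from EMG and theta/delta ratio.

    Deterministic given the spectra (no randomness).  Artifact flags are
    carried over from the spectra; artifact epochs are still scored.
    """
    if spectra.emg_rms is None or len(spectra.emg_rms) != spectra.n_epochs:
        raise ValueError("spectra must carry per-epoch EMG RMS values")
    log_emg = np.log10(np.asarray(spectra.emg_rms, dtype=float) + 1e-12)
    emg_thr = _threshold(log_emg, emg_fallback_quantile, "EMG split")
    wake = log_emg > emg_thr

    # theta/delta ratio on raw (unflagged) powers: states must always be
    # determinable, artifacts only exclude epochs from spectral averages.
    delta = spectra.power[:, DELTA.mask()].sum(axis=1)
    theta = spectra.power[:, THETA.mask()].sum(axis=1)
    log_ratio = np.log10((theta + 1e-12) / (delta + 1e-12))
    sleep = ~wake
    if np.any(sleep):
        ratio_thr = _threshold(log_ratio[sleep], ratio_fallback_quantile, "theta/delta split")
    else:
        ratio_thr = np.inf

    states = np.full(spectra.n_epochs, NREM, dtype=np.int8)
    states[wake] = WAKE
    states[sleep & (log_ratio > ratio_thr)] = REM
    if smooth:
        states = _majority_smooth(states)
    return Hypnogram(
        states=states,
        artifact=spectra.artifact.copy(),
        epoch_seconds=spectra.epoch_seconds,
        start_zt_h=spectra.start_zt_h,
    )


def _interval_label(bin_start_zt: float) -> str:
    day = int(bin_start_zt // 24.0)
    phase = "L" if (bin_start_zt % 24.0) < 12.0 else "D"
    return f"{phase}{day + 1}"


def state_percent_timecourse(
    hyp: Hypnogram,
    bin_hours: float = 2.0,
    allow_partial: bool = False,
) -> StateTimecourse:
    """Percentage of recording time per state in ZT-aligned clock bins.

    Bins are half-open [start, start + bin_hours) anchored at the
    hypnogram's start ZT.  A trailing partial bin is rejected unless
    ``allow_partial`` is set.  Epoch counts are conserved: summed over
    bins they reproduce the hypnogram's totals.
    """
    if bin_hours <= 0:
        raise ValueError("bin_hours must be positive")
    epochs_per_bin = bin_hours * 3600.0 / hyp.epoch_seconds
    if abs(epochs_per_bin - round(epochs_per_bin)) > 1e-9:
        raise ValueError("bin_hours must hold a whole number of epochs")
    n_full, rem_ = divmod(hyp.n_epochs, int(round(epochs_per_bin)))
    if rem_ and not allow_partial:
        raise ValueError(
            f"recording does not cover whole {bin_hours}-h bins "
            f"({rem_} trailing epochs); pass allow_partial=True to keep them"
        )
    n_bins = n_full + (1 if rem_ and allow_partial else 0)
    if n_bins == 0:
        raise ValueError("recording shorter than one bin")

    idx = (np.arange(hyp.n_epochs) // int(round(epochs_per_bin))).astype(int)
    counts = np.zeros((n_bins, 3), dtype=int)
    n_artifact = np.zeros(n_bins, dtype=int)
    for s in (WAKE, NREM, REM):
        counts[:, s] = np.bincount(idx[hyp.states == s], minlength=n_bins)
    n_artifact = np.bincount(idx[hyp.artifact], minlength=n_bins)
    totals = counts.sum(axis=1)
    percent = 100.0 * counts / totals[:, None]
    starts = hyp.start_zt_h + np.arange(n_bins) * bin_hours
    labels = [_interval_label(s) for s in starts]
    return StateTimecourse(
        bin_start_zt_h=starts,
        percent=percent,
        counts=counts,
        n_artifact=n_artifact,
        bin_hours=bin_hours,
        interval_labels=labels,
    )


def waking_peak(
    tc: StateTimecourse,
    interval: tuple[float, float] = (12.0, 24.0),
    state: int = WAKE,
) -> PeakResult:
    """Midpoint of the maximal 2-h bin of a state inside an interval.

    The default interval is the dark/dim half of the first day.  Ties
    resolve to the earliest bin.
    """
    if abs(tc.bin_hours - 2.0) > 1e-9:
        raise ValueError("waking_peak expects a 2-h resolution timecourse")
    lo, hi = interval
    sel = (tc.bin_start_zt_h >= lo - 1e-9) & (tc.bin_start_zt_h + tc.bin_hours <= hi + 1e-9)
    if not np.any(sel):
        raise ValueError(f"no whole bins inside interval [{lo}, {hi}) h")
    vals = tc.percent[sel, state]
    starts = tc.bin_start_zt_h[sel]
    best = int(np.argmax(vals))  # argmax returns the first maximum: earliest bin
    return PeakResult(
        peak_zt_h=float(starts[best] + tc.bin_hours / 2.0),
        peak_value=float(vals[best]),
        search_interval=(float(lo), float(hi)),
    )


def daily_amplitude(tc: StateTimecourse) -> AmplitudeResult:
    """Dark-phase mean % − light-phase mean % per state over the first 24 h.

    Requires a timecourse whose bins tile a full baseline day with a
    whole number of bins per 12-h phase.
    """
    per_phase = 12.0 / tc.bin_hours
    if abs(per_phase - round(per_phase)) > 1e-9:
        raise ValueError("bin_hours must divide the 12-h phase")
    zt = tc.bin_start_zt_h % 24.0
    day0 = tc.bin_start_zt_h < 24.0
    light = day0 & (zt < 12.0)
    dark = day0 & (zt >= 12.0)
    if light.sum() != per_phase or dark.sum() != per_phase:
        raise ValueError("timecourse must cover a full 24-h baseline day")
    diffs = tc.percent[dark].mean(axis=0) - tc.percent[light].mean(axis=0)
    return AmplitudeResult(wake=float(diffs[WAKE]), nrem=float(diffs[NREM]), rem=float(diffs[REM]))


def compare_recovery_to_baseline(bl: StateTimecourse, rec: StateTimecourse) -> pd.DataFrame:
    """Paired per-bin recovery − baseline differences, per state.

    Both timecourses must share bin width and bin count (aligned by
    position: bin *i* of the recovery day is compared with bin *i* of
    the baseline day, i.e. the same clock time).  Returns a long-format
    frame ready for paired tests.
    """
    if abs(bl.bin_hours - rec.bin_hours) > 1e-9 or bl.n_bins != rec.n_bins:
        raise ValueError("baseline and recovery timecourses are misaligned")
    rows = []
    for b in range(bl.n_bins):
        for s in (WAKE, NREM, REM):
            rows.append(
                {
                    "bin_start_zt": float(bl.bin_start_zt_h[b] % 24.0),
                    "interval": rec.interval_labels[b] if rec.interval_labels else "",
                    "state": STATE_LABELS[s],
                    "baseline": float(bl.percent[b, s]),
                    "recovery": float(rec.percent[b, s]),
                    "difference": float(rec.percent[b, s] - bl.percent[b, s]),
                }
            )
    return pd.DataFrame(rows)
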