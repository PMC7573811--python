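"""File formats: activity CSV, hypnogram CSV, EDF signals, result tables.

Activity traces travel as ``timestamp_iso,count`` CSV; hypnograms as
``epoch_start_s,state,artifact`` CSV with state in {W, N, R}.  EEG/EMG
recordings are written as plain EDF (European Data Format): 2 signals
labelled EEG and EMG at 128 Hz, 4-s data records, 16-bit samples.  The
EDF writer/reader here implements the standard fixed-layout header
directly; round trips are byte-stable and readable by standard EDF
tools.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .actigraphy import DFAResult, PeriodogramResult
from .core import (
    EPOCH_SECONDS,
    SAMPLE_RATE_HZ,
    STATE_LABELS,
    ActivityTrace,
    Hypnogram,
    LightSchedule,
    SignalRecording,
)

__all__ = [
    "write_activity_csv",
    "read_activity_csv",
    "write_hypnogram_csv",
    "read_hypnogram_csv",
    "write_edf",
    "read_edf",
    "periodogram_to_json",
    "dfa_to_json",
]

_STATE_TO_CODE = {label: code for code, label in enumerate(STATE_LABELS)}


def write_activity_csv(trace: ActivityTrace, path: str | Path, day0: str = "2020-01-01") -> None:
    """Write ``timestamp_iso,count`` rows; timestamps anchor ZT0 to the
    schedule's lights-on clock time on ``day0``."""
    t0 = trace.schedule.lights_on_datetime(day0) + timedelta(hours=trace.start_zt_h)
    stamps = [t0 + timedelta(seconds=i * trace.bin_seconds) for i in range(trace.n_bins)]
    df = pd.DataFrame({"timestamp_iso": [s.isoformat() for s in stamps], "count": trace.counts})
    df.to_csv(path, index=False)


def read_activity_csv(path: str | Path, schedule: LightSchedule | None = None) -> ActivityTrace:
    """Read an activity CSV; bin size is inferred from the timestamps.

    Gaps are rejected: every consecutive pair of timestamps must be one
    bin apart (impute or split upstream).
    """
    df = pd.read_csv(path)
    if not {"timestamp_iso", "count"} <= set(df.columns):
        raise ValueError("activity CSV needs columns timestamp_iso,count")
    times = pd.to_datetime(df["timestamp_iso"])
    if len(times) < 2:
        raise ValueError("need at least 2 bins")
    deltas = times.diff().dropna().dt.total_seconds().to_numpy()
    bin_s = deltas[0]
    if np.any(np.abs(deltas - bin_s) > 1e-6):
        raise ValueError("activity CSV has missing or irregular bins")
    schedule = schedule or LightSchedule()
    lights_on = schedule.lights_on_datetime(times.iloc[0].date().isoformat())
    start_zt = (times.iloc[0].to_pydatetime() - lights_on).total_seconds() / 3600.0 % 24.0
    return ActivityTrace(
        counts=df["count"].to_numpy(float),
        bin_seconds=float(bin_s),
        start_zt_h=float(start_zt),
        schedule=schedule,
    )


def write_hypnogram_csv(hyp: Hypnogram, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "epoch_start_s": np.arange(hyp.n_epochs) * hyp.epoch_seconds,
            "state": [STATE_LABELS[s] for s in hyp.states],
            "artifact": hyp.artifact.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_hypnogram_csv(path: str | Path, schedule: LightSchedule | None = None) -> Hypnogram:
    df = pd.read_csv(path)
    if not {"epoch_start_s", "state", "artifact"} <= set(df.columns):
        raise ValueError("hypnogram CSV needs columns epoch_start_s,state,artifact")
    try:
        states = np.array([_STATE_TO_CODE[s] for s in df["state"]], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"unknown state label {exc.args[0]!r}; expected W/N/R") from None
    starts = df["epoch_start_s"].to_numpy(float)
    epoch_s = float(starts[1] - starts[0]) if len(starts) > 1 else float(EPOCH_SECONDS)
    return Hypnogram(
        states=states,
        artifact=df["artifact"].to_numpy(bool),
        epoch_seconds=epoch_s,
        schedule=schedule or LightSchedule(),
    )


def _pad(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: SignalRecording, path: str | Path, day0: str = "2020-01-01") -> None:
    """Write a 2-signal (EEG, EMG) EDF file with 4-s data records.

    Physical range per signal spans the data symmetrically; digital
    range is the full 16-bit span, so quantisation error is
    (phys range) / 65535 per sample.
    """
    n_rec = rec.n_epochs
    spr = int(rec.sample_rate_hz * EPOCH_SECONDS)  # samples per record per signal
    start = rec.schedule.lights_on_datetime(day0) + timedelta(hours=rec.start_zt_h)
    signals = [("EEG", rec.eeg), ("EMG", rec.emg)]

    header = bytearray()
    header += _pad("0", 8)
    header += _pad("X X X X", 80)  # anonymous patient
    header += _pad("Startdate X X X X", 80)
    header += _pad(start.strftime("%d.%m.%y"), 8)
    header += _pad(start.strftime("%H.%M.%S"), 8)
    header += _pad(str(256 * (1 + len(signals))), 8)
    header += _pad("", 44)
    header += _pad(str(n_rec), 8)
    header += _pad(str(EPOCH_SECONDS), 8)
    header += _pad(str(len(signals)), 4)

    phys = []
    digital = []
    for _, x in signals:
        lim = max(1.0, float(np.max(np.abs(x))) * 1.001)
        phys.append(lim)
        q = np.clip(np.round(x / lim * 32767.0), -32767, 32767).astype("<i2")
        digital.append(q.reshape(n_rec, spr))

    def field(values: list[str], width: int) -> bytes:
        return b"".join(_pad(v, width) for v in values)

    names = [n for n, _ in signals]
    header += field(names, 16)
    header += field(["" for _ in signals], 80)  # transducer
    header += field(["uV" for _ in signals], 8)
    header += field([f"{-l:.6g}"[:8] for l in phys], 8)
    header += field([f"{l:.6g}"[:8] for l in phys], 8)
    header += field(["-32767" for _ in signals], 8)
    header += field(["32767" for _ in signals], 8)
    header += field(["" for _ in signals], 80)  # prefiltering
    header += field([str(spr) for _ in signals], 8)
    header += field(["" for _ in signals], 32)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # records interleave signals: all EEG samples of record r, then EMG
        for r in range(n_rec):
            for q in digital:
                fh.write(q[r].tobytes())


def read_edf(path: str | Path, schedule: LightSchedule | None = None) -> SignalRecording:
    """Read a 2-signal EDF written by :func:`write_edf` (or any EDF whose
    first two signals are EEG/EMG at 128 Hz with equal record layout)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_rec = int(head[236:244].decode().strip())
        ns = int(head[252:256].decode().strip())
        sig_head = fh.read(256 * ns)

        def col(offset: int, width: int) -> list[str]:
            base = offset * ns
            return [
                sig_head[base + i * width : base + (i + 1) * width].decode().strip()
                for i in range(ns)
            ]

        # field offsets: label 16, transducer 80, dim 8, pmin 8, pmax 8,
        # dmin 8, dmax 8, prefilter 80, spr 8, reserved 32 — cumulative:
        off = {"pmin": 16 + 80 + 8, "pmax": 16 + 80 + 8 + 8, "dmin": 16 + 80 + 8 + 16,
               "dmax": 16 + 80 + 8 + 24, "spr": 16 + 80 + 8 + 32 + 80}
        phys_min = [float(v) for v in col(off["pmin"], 8)]
        phys_max = [float(v) for v in col(off["pmax"], 8)]
        dig_min = [int(v) for v in col(off["dmin"], 8)]
        dig_max = [int(v) for v in col(off["dmax"], 8)]
        spr = [int(v) for v in col(off["spr"], 8)]
        data = np.frombuffer(fh.read(), dtype="<i2")

    per_rec = sum(spr)
    data = data[: n_rec * per_rec].reshape(n_rec, per_rec)
    signals = []
    pos = 0
    for i in range(ns):
        raw = data[:, pos : pos + spr[i]].astype(float).ravel()
        scale = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        signals.append(phys_min[i] + (raw - dig_min[i]) * scale)
        pos += spr[i]
    if ns < 2:
        raise ValueError("expected at least EEG and EMG signals")
    return SignalRecording(
        eeg=signals[0],
        emg=signals[1],
        schedule=schedule or LightSchedule(),
        sample_rate_hz=float(SAMPLE_RATE_HZ),
    )


def write_spectra_tsv(spectra, path: str | Path) -> None:
    """Write per-epoch spectra as TSV: epoch index, artifact flag,
    EMG RMS, then one column per 0.25-Hz bin (100 columns)."""
    cols = {f"p{f:.2f}Hz": spectra.power[:, i] for i, f in enumerate(spectra.freq_bins_hz)}
    df = pd.DataFrame(
        {
            "epoch": np.arange(spectra.n_epochs),
            "artifact": spectra.artifact.astype(int),
            "emg_rms": spectra.emg_rms,
            **cols,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def periodogram_to_json(res: PeriodogramResult, path: str | Path) -> None:
    payload = {
        "periods_h": res.periods_h.tolist(),
        "statistic": res.statistic.tolist(),
        "threshold": res.threshold.tolist(),
        "peak_period_h": res.peak_period_h,
        "strength": res.strength,
        "significant": res.significant,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def dfa_to_json(res: DFAResult, path: str | Path) -> None:
    payload = asdict(res)
    for key, val in payload.items():
        if isinstance(val, np.ndarray):
            payload[key] = val.tolist()
    Path(path).write_text(json.dumps(payload, indent=1))
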