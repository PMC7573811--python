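"""End-to-end study pipeline: simulate arms, analyse, report.

A config (YAML mapping or plain dict) declares the study arms —
control light:dark plus dim-light-at-night (DLAN) arms of increasing
exposure — with per-arm generator settings (disruption, phase delay,
night lux), group sizes and a master seed.  ``run_pipeline`` simulates
every animal, runs the actigraphy, spectral and vigilance stages, and
assembles result tables plus a statistics report.  The whole run is
reproducible from config + seed; per-animal seeds are derived
deterministically from the master seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .actigraphy import dfa, periodogram
from .core import LightSchedule
from .spectral import (
    SWA_BROAD,
    BandDefinition,
    detect_artifacts,
    epoch_and_fft,
    swa_timecourse,
)
from .stats import anova, bonferroni_ttests, fit_delay_regression
from .synthetic import (
    ActivityGenParams,
    EEGGenParams,
    SDProtocol,
    simulate_activity,
    simulate_recording,
)
from .vigilance import (
    daily_amplitude,
    score_epochs,
    state_percent_timecourse,
    waking_peak,
)

__all__ = ["default_config", "run_pipeline"]

log = logging.getLogger("noxlux")


def default_config() -> dict[str, Any]:
    """A small demo configuration: control + two DLAN arms, 2 animals each."""
    return {
        "seed": 1,
        "arms": [
            {"name": "control_LD", "n": 2, "night_lux": 0.0, "disruption": 0.0,
             "phase_delay_h": 0.0, "exposure_days": 0},
            {"name": "dlan_1m", "n": 2, "night_lux": 5.0, "disruption": 0.5,
             "phase_delay_h": 4.0, "exposure_days": 30},
            {"name": "dlan_3m", "n": 2, "night_lux": 5.0, "disruption": 0.9,
             "phase_delay_h": 6.0, "exposure_days": 90},
        ],
        "activity": {"days": 15, "bin_seconds": 60, "mean_rate": 50.0,
                     "circadian_amplitude": 0.9, "fractal_beta": 1.0},
        "eeg": {"days": 2, "sd": {"start_zt_h": 0.0, "duration_h": 6.0}},
        "dfa_fit_range_h": [3.0, 8.0],
        "periodogram_grid_h": [20.0, 28.0, 0.05],
        "swa_band_hz": [0.5, 4.0],
    }


def _animal_seed(base: int, arm_i: int, animal_i: int) -> int:
    return (base * 1_000 + arm_i * 100 + animal_i) % (2**31 - 1)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run the full simulated study and write tables + a stats report.

    Returns the report dict; writes per-stage TSV tables and
    ``stats_report.json`` under ``out_dir``.  Any stage failure aborts
    with the arm/animal identity in the exception message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    act_cfg = dict(config.get("activity", {}))
    eeg_cfg = dict(config.get("eeg", {}))
    fit_lo, fit_hi = config.get("dfa_fit_range_h", [3.0, 8.0])
    g0, g1, gstep = config.get("periodogram_grid_h", [20.0, 28.0, 0.05])
    grid = np.arange(g0, g1 + 1e-9, gstep)
    swa_lo, swa_hi = config.get("swa_band_hz", [0.5, 4.0])
    swa_band = BandDefinition("swa", swa_lo, swa_hi) if (swa_lo, swa_hi) != (0.5, 4.0) else SWA_BROAD
    sd_cfg = eeg_cfg.get("sd")
    sd = SDProtocol(**sd_cfg) if sd_cfg else None
    eeg_days = int(eeg_cfg.get("days", 2))

    act_rows, eeg_rows, swa_rows, tc_rows = [], [], [], []
    rebound_rows = []
    for arm_i, arm in enumerate(config["arms"]):
        schedule = LightSchedule(night_lux=float(arm.get("night_lux", 0.0)))
        for animal_i in range(int(arm["n"])):
            aseed = _animal_seed(seed, arm_i, animal_i)
            ident = f"{arm['name']}/animal{animal_i}"
            log.info("simulating %s (seed %d)", ident, aseed)
            try:
                ap = ActivityGenParams(
                    days=int(act_cfg.get("days", 15)),
                    bin_seconds=float(act_cfg.get("bin_seconds", 60)),
                    mean_rate=float(act_cfg.get("mean_rate", 50.0)),
                    circadian_amplitude=float(act_cfg.get("circadian_amplitude", 0.9)),
                    fractal_beta=float(act_cfg.get("fractal_beta", 1.0)),
                    phase_delay_h=float(arm.get("phase_delay_h", 0.0)),
                    disruption=float(arm.get("disruption", 0.0)),
                    seed=aseed,
                )
                trace = simulate_activity(ap, schedule)
                d = dfa(trace, (float(fit_lo), float(fit_hi)))
                p = periodogram(trace, grid)
                act_rows.append(
                    {"arm": arm["name"], "animal": animal_i, "alpha": d.alpha,
                     "fit_r2": d.fit_r2, "peak_period_h": p.peak_period_h,
                     "strength": p.strength, "significant": p.significant}
                )

                ep = EEGGenParams(
                    days=eeg_days,
                    phase_delay_h=float(arm.get("phase_delay_h", 0.0)),
                    seed=aseed + 7,
                )
                rec, truth = simulate_recording(ep, schedule, sd)
                spectra = detect_artifacts(epoch_and_fft(rec), rec)
                scored = score_epochs(spectra)
                agreement = float(np.mean(scored.states == truth.states))
                tc2 = state_percent_timecourse(scored, 2.0)
                amp = daily_amplitude(tc2)
                peak = waking_peak(tc2, (12.0, 24.0))
                swa = swa_timecourse(spectra, scored, swa_band, 2.0)
                eeg_rows.append(
                    {"arm": arm["name"], "animal": animal_i,
                     "scoring_agreement": agreement,
                     "waking_peak_zt_h": peak.peak_zt_h,
                     "amp_wake": amp.wake, "amp_nrem": amp.nrem, "amp_rem": amp.rem,
                     "exposure_days": arm.get("exposure_days", 0)}
                )
                for b in range(tc2.n_bins):
                    tc_rows.append(
                        {"arm": arm["name"], "animal": animal_i,
                         "bin_start_zt": tc2.bin_start_zt_h[b],
                         "interval": tc2.interval_labels[b],
                         "WAKE": tc2.percent[b, 0], "NREM": tc2.percent[b, 1],
                         "REM": tc2.percent[b, 2]}
                    )
                for b in range(len(swa.swa)):
                    swa_rows.append(
                        {"arm": arm["name"], "animal": animal_i,
                         "bin_start_zt": swa.bin_start_zt_h[b], "swa": swa.swa[b],
                         "n_nrem_epochs": swa.n_epochs[b]}
                    )
                if sd is not None and eeg_days >= 2:
                    # first 2-h recovery bin vs same clock time on baseline
                    rec_zt = 24.0 + sd.start_zt_h + sd.duration_h
                    bl_i = int(np.argmin(np.abs(swa.bin_start_zt_h - (sd.start_zt_h + sd.duration_h))))
                    rec_i = int(np.argmin(np.abs(swa.bin_start_zt_h - rec_zt)))
                    rebound_rows.append(
                        {"arm": arm["name"], "animal": animal_i,
                         "baseline_swa": swa.swa[bl_i], "recovery_swa": swa.swa[rec_i],
                         "rebound_ratio": swa.swa[rec_i] / swa.swa[bl_i]}
                    )
            except Exception as exc:  # noqa: BLE001 — re-raise with identity
                raise RuntimeError(f"pipeline stage failed for {ident}: {exc}") from exc

    act_df = pd.DataFrame(act_rows)
    eeg_df = pd.DataFrame(eeg_rows)
    act_df.to_csv(out / "actigraphy.tsv", sep="\t", index=False)
    eeg_df.to_csv(out / "sleep_summary.tsv", sep="\t", index=False)
    pd.DataFrame(tc_rows).to_csv(out / "timecourse_2h.tsv", sep="\t", index=False)
    pd.DataFrame(swa_rows).to_csv(out / "swa_2h.tsv", sep="\t", index=False)
    if rebound_rows:
        pd.DataFrame(rebound_rows).to_csv(out / "swa_rebound.tsv", sep="\t", index=False)

    report: dict[str, Any] = {"seed": seed, "arms": [a["name"] for a in config["arms"]]}
    by_arm = act_df.groupby("arm", sort=False)
    report["alpha_by_arm"] = by_arm["alpha"].mean().to_dict()
    report["strength_by_arm"] = by_arm["strength"].mean().to_dict()
    report["scoring_agreement_mean"] = float(eeg_df["scoring_agreement"].mean())

    if len(config["arms"]) >= 2 and act_df["arm"].nunique() >= 2 and all(
        int(a["n"]) >= 2 for a in config["arms"]
    ):
        for metric in ("alpha", "strength"):
            tbl = anova(act_df, metric, ["arm"])
            report[f"anova_{metric}"] = {
                "F": tbl.f_value("arm"), "p": tbl.p_value("arm"),
            }
        control = config["arms"][0]["name"]
        others = [a["name"] for a in config["arms"][1:]]
        groups = {name: g["alpha"].to_numpy() for name, g in by_arm}
        plan = [(control, o) for o in others]
        comps = bonferroni_ttests(groups, plan)
        report["alpha_vs_control"] = [
            {"pair": [c.group_a, c.group_b], "t": c.t, "p_raw": c.p_raw,
             "p_adjusted": c.p_adjusted} for c in comps
        ]

    if eeg_df["exposure_days"].nunique() >= 3:
        # exposure index 1..k (ranked durations), as in delay-vs-exposure fits
        idx = {d: i + 1 for i, d in enumerate(sorted(eeg_df["exposure_days"].unique()))}
        x = eeg_df["exposure_days"].map(idx).to_numpy(float)
        y = eeg_df["waking_peak_zt_h"].to_numpy(float)
        fit = fit_delay_regression(x, y)
        report["waking_peak_vs_exposure"] = {
            "slope": fit.slope, "slope_se": fit.slope_se,
            "intercept": fit.intercept, "r_squared": fit.r_squared,
        }
    if rebound_rows:
        rdf = pd.DataFrame(rebound_rows)
        report["swa_rebound_ratio_by_arm"] = rdf.groupby("arm", sort=False)[
            "rebound_ratio"
        ].mean().to_dict()

    (out / "stats_report.json").write_text(json.dumps(_jsonable(report), indent=1))
    log.info("pipeline complete: %s", out)
    return report
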