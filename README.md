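# noxlux

Rest-activity and sleep-EEG analysis for light-at-night rodent studies.

Chronic exposure to dim light at night (DLAN, ~5 lux replacing the dark
phase) degrades circadian organisation in mice: rest-activity rhythms
weaken, the nightly waking peak drifts later, and the sleep EEG loses
power in its prominent frequency bands.  `noxlux` implements the full
quantitative chain used to measure those effects, for chronobiologists
and sleep researchers who want a tested, scriptable pipeline:

* **Actigraphy** — folded (chi-square style) periodogram for circadian
  period and rhythm strength, and detrended fluctuation analysis (DFA)
  of locomotor counts.  DFA integrates the mean-centred counts,
  detrends non-overlapping windows of size *n*, pools the RMS residual
  into F(*n*), and fits α as the slope of log F(*n*) vs log *n* over
  the 3–8 h circadian range; α ≈ 1 marks healthy scale-invariant
  behaviour, α → 0.5 uncorrelated noise.
* **Sleep EEG** — 4-s-epoch FFT spectra (0.25–25 Hz, exact Parseval
  scaling), artifact flagging, band powers (delta 0.75–4 Hz, theta
  6.25–9 Hz), per-state mean spectra, and 2-h NREM slow-wave-activity
  (SWA) timecourses.
* **Vigilance states** — rule-based WAKE/NREM/REM scoring of 4-s
  epochs from EMG and the theta/delta ratio, state-percentage
  timecourses, waking-peak location, day–night amplitudes, and
  baseline-vs-recovery comparisons around a 6-h sleep deprivation.
* **Statistics** — fixed-effects ANOVA (Type-II SS), Bonferroni-corrected
  paired/Welch t-tests, and OLS regression of waking-peak delay on
  exposure duration.
* **Synthetic data** — generators with known ground truth (injected
  fractal exponent β with target α = (β+1)/2, programmed period, phase
  delay, Markov-chain hypnograms, a Process-S homeostat, and a forced-
  wake protocol) so every stage of the chain is verifiable without any
  animal data.

## Worked example

Simulate a 15-day control trace and analyse it:

```python
from noxlux import ActivityGenParams, simulate_activity, periodogram, dfa

trace = simulate_activity(ActivityGenParams(seed=3))   # 12:12 LD control
p = periodogram(trace)                                  # grid 20-28 h, 0.05 h
d = dfa(trace, fit_range_h=(3.0, 8.0))
print(f"period {p.peak_period_h:.2f} h, strength {p.strength:.3f}, "
      f"significant={p.significant}")
print(f"alpha {d.alpha:.3f} (fit R2 {d.fit_r2:.3f})")
```

```
period 24.00 h, strength 0.242, significant=True
alpha 1.015 (fit R2 0.988)
```

The peak sits exactly on the entrained 24-h period, the rhythm is far
above the chi-square significance line, and α ≈ 1 reflects the pink
(1/f) fractal component injected by the generator — the signature of a
healthy control animal.

The same from the shell, plus a full simulated study (control + two
DLAN arms, baseline day + 6-h sleep deprivation day):

```bash
noxlux simulate-activity --seed 3 --days 15 -o act.csv
noxlux dfa act.csv --fit-lo 3 --fit-hi 8
noxlux demo -o demo_out
```

`demo` writes per-animal tables (`actigraphy.tsv`, `timecourse_2h.tsv`,
`swa_2h.tsv`, `swa_rebound.tsv`) and `stats_report.json`.  With the
default seed the report shows the expected disruption gradient — mean
α 1.071 > 0.991 > 0.937 and rhythm strength 0.240 > 0.105 > 0.061
across control → 1-month → 3-month DLAN analogues — a ~5–6× SWA
rebound in the first 2-h bin after sleep deprivation in every arm, and
99.9% agreement between the automatic scorer and the simulator's
ground-truth hypnograms.

A YAML config with custom arms, group sizes, bands and comparison plans
runs through `noxlux run config.yaml -o out/` (see
`noxlux.pipeline.default_config()` for the schema; a seed is
mandatory).

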