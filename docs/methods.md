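# Methods

This note describes the models and numerical procedures implemented in
`noxlux`, the assumptions behind them, and what the synthetic-data
generators do and do not emulate.

## Study design being emulated

The package targets the analysis chain of a rodent dim-light-at-night
(DLAN) experiment: mice kept on a 12:12 h light:dark cycle (75:0 lux,
lights on 10:00) or a 12:12 h light:DLAN cycle (75:5 lux), with
(a) passive-infrared (PIR) locomotor counts recorded for ~15 days and
(b) EEG/EMG recorded across a baseline day followed by 6 h of enforced
wakefulness from light onset and an 18-h recovery period.  Zeitgeber
time (ZT) is used throughout: ZT0 = lights-on, ZT12 = dark/dim onset.
Lux values are carried as labels only; nothing models
phototransduction, melatonin, temperature or feeding.

## Rest-activity analysis

### Folded periodogram

For each candidate period `P` on a grid (default 20–28 h in 0.05-h
steps) the count series is folded at `P` into `C = 288` equal phase
columns (5-min phase resolution at 24 h) and the statistic is

    eta²(P) = SS_between(P) / SS_total,

the fraction of total variance explained by the folded mean waveform.
The peak period is the grid argmax; rhythm strength is `eta²` at the
peak.  A fixed column count keeps the white-noise expectation of the
statistic, `(C−1)/N`, identical across the grid so the argmax is
unbiased in period; continuous phase assignment handles non-integer
periods in bins.  Under the white-noise null `N·eta² ≈ χ²(C−1)`, which
gives the per-period significance threshold; the default threshold is
Bonferroni-corrected over the grid size, so the *peak* statistic can be
compared against the threshold at a familywise 0.05 level.  (With a
pointwise threshold the maximum over ~160 correlated periods exceeds
the line by chance alone.)

The classical chi-square/F periodogram literature uses the same folding
construction; absolute strength values depend on the column count and
noise bandwidth and are not comparable across implementations — only
orderings and significance calls are contracted.

### Detrended fluctuation analysis (DFA-1)

The counts are mean-centred and cumulatively summed to a profile; the
profile is split into non-overlapping windows of size `n` (one forward
pass, trailing remainder discarded); each window is least-squares
linearly detrended; `F(n)` is the RMS residual pooled over windows.
Window sizes are ~16 log-spaced values inside the fit range plus
diagnostic sizes half a decade either side.  The scaling exponent `α`
is the OLS slope of `log10 F(n)` vs `log10 n` restricted to the 3–8 h
range — the circadian range that stays statistically reliable for
15-day recordings; every fitted size is required to have ≥ 4 windows,
and shorter inputs warn.  `α ≈ 0.5` indicates uncorrelated counts,
`α ≈ 1` the scale-invariant correlations of healthy rest-activity
control, `α ≈ 1.5` Brownian-type integration.  DFA-1 is exactly
invariant under affine transforms of the input.

## Activity generator

Counts are Poisson draws around a non-negative intensity

    λ(t) = r · g(t) · max(0, 1 + c·z(t) + d(t)),

with mean rate `r` (default 200 counts/min), a nocturnal square gate
`g`, a fractal modulation `z`, and disruption noise `d`.

* **Gate.** `g = 1 ± (2/3)·a` (active/rest) with circadian amplitude
  `a ∈ [0,1]`, default 0.9.  The active window is the dark half,
  shifted later by `phase_delay_h` (circularly, so a delayed animal
  remains active into early light).  The onset/offset edges are
  deliberately sharp: entrained rodent activity starts abruptly at
  lights-off, and those edges are what pins the periodogram peak to
  the period grid cell containing 24.00 h.  The half-swing factor 2/3
  keeps the gate's square-wave harmonics (8, 4.8, 3.43 h — inside the
  DFA fit band) small relative to the fractal fluctuations, so the
  gate biases `α` by ≲ +0.05 at control settings.
* **Fractal component.** `z` is synthesized spectrally: complex
  Gaussian coefficients with amplitude ∝ `f^(−β/2)`, giving a power
  spectral density ∝ `f^(−β)` and a target DFA exponent
  `α = (β+1)/2`; `β = 1` (pink) targets the healthy `α = 1`.  `z` is
  normalised to unit RMS of its 1.5–16 h band-passed component — a
  band bracketing the 3–8 h fit range — so the fluctuation magnitude
  at the analysed timescales is the same for every `β` (total-variance
  normalisation would let the lowest frequencies dominate for steep
  spectra and make the exponent unrecoverable).  Default modulation
  depth `c = 1.0`.
* **Zeitgeber re-anchoring.** For entrained conditions `z` is built
  from independent half-day blocks (`anchor_block_h = 12`): the light
  schedule re-synchronises behaviour at every transition, so
  behavioural fluctuations carry no free-running phase coherence
  across days.  Without this, fractal power in the 20–28 h band makes
  the periodogram peak wander by one or two grid steps.  For
  free-running or arrhythmic simulations (`circadian_amplitude = 0`)
  set `anchor_block_h = None` to keep full spectral coherence; the
  exponent-recovery tests use that mode.
* **Disruption.** `disruption ∈ [0,1]` scales the gate amplitude by
  `(1−disruption)` and adds white noise of RMS `disruption·c` to the
  night-phase modulation.  Both effects lower rhythm strength, and the
  added white noise pulls `α` toward 0.5, reproducing the direction of
  the published group ordering (control > 1-month > 3-month DLAN for
  both strength and `α`).

With these defaults the control condition yields strength ≈ 0.22–0.25
and `α ≈ 1.05 ± 0.05`; the periodogram peak is exactly 24.00 h in
≈ 95% of seeds (the group median is used as the period estimate, as a
robust analogue of the published mean ± SD of 24.0 ± 0.0 h).

## EEG/EMG generator

### Hypnogram

Vigilance states (WAKE/NREM/REM) evolve as a first-order Markov chain
in 4-s epochs with separate transition matrices for three regimes:
light phase, dark (active) phase, and a 2-h "surge" window at the
(possibly delayed) active-phase onset with strongly elevated waking —
this surge produces the waking peak whose delay tracks
`phase_delay_h`.  Direct WAKE→REM transitions are disallowed by
default (standard rodent convention), and dark-phase hours before a
delayed onset use the rest-phase matrix.  Default stationary structure:
~60% waking per 24 h, waking dominant in the dark, REM ~6%.

A two-process coupling links the chain to sleep pressure: the
WAKE→NREM transition probability is scaled by
`1 + coupling·(S − S_ref)` (defaults 1.5 and 0.35), so elevated
pressure after sleep deprivation shortens waking bouts and produces an
NREM rebound in the recovery period, as observed experimentally.  REM
pressure is not modelled.

### Process S homeostat

`S ∈ [0,1]` relaxes exponentially toward 1 during WAKE and REM epochs
with `τ_rise = 8 h` and toward 0 during NREM epochs with
`τ_decay = 2 h` (each 4-s epoch applies one exact exponential step;
`S₀ = 0.5`).  The literature motivates a saturating-exponential
two-process form but fixes no parameters; these values produce a clear
SWA rebound in the first 2-h recovery bin after 6-h sleep deprivation
and a realistic daily SWA modulation (discharge across the light
phase, rebuild across the dark phase, maximum near the dark→light
transition).

### Signals

Each epoch's EEG is coloured noise synthesized in the frequency
domain: complex Gaussian coefficients on the 0.25–25 Hz grid (0.25-Hz
bins, one rfft bin each at 512 samples/epoch and 128 Hz) scaled so the
expected bin power equals the state's spectral template.  Templates:
NREM peaks in the delta band (Gaussian bump at 2 Hz over a 1/f
background, 250 µV² total), REM in the theta band (7.5 Hz, 120 µV²),
WAKE broadband 1/f with a modest theta component (120 µV²).  The NREM
slow-wave (0.5–4 Hz) amplitude is multiplied by `gain·S(t)`
(`gain = 2`).  EMG is white noise with state-dependent RMS
(WAKE 40 ≫ NREM 6 ≥ REM 4 µV).  Epochs are synthesized independently;
no phase continuity across epoch boundaries is modelled.

## EEG analysis

* **Spectra.** One rectangular-window FFT per 4-s epoch; power scaled
  so that the sum over all non-DC bins equals the epoch variance
  (discrete Parseval, exact to float precision).  Bins 0.25–25.0 Hz
  are retained (100 bins); the 25.25–64 Hz remainder is kept as a
  per-epoch scalar so the Parseval identity stays checkable.  No
  tapering: it would break exact Parseval bookkeeping and the emulated
  acquisition chain used a plain FFT.
* **Bands.** Inclusive edges on the 0.25-Hz grid: delta 0.75–4.0 Hz,
  theta 6.25–9.0 Hz; SWA ships in two presets (0.5–4.0 and
  0.75–4.0 Hz) because both conventions appear in the source
  literature; the broad preset is the default.
* **Artifacts.** An epoch is flagged when its peak deviation exceeds
  6 robust SDs (1.4826·MAD) of the recording or it is flatline.
  Flags exclude epochs from spectral averages only — states are always
  scored.  The criterion is this package's own; real artifact
  processes (chewing, cable noise) are not emulated, so the <1%
  false-positive rate measured on simulator output says nothing about
  real-data sensitivity.
* **State spectra and SWA timecourse.** Mean spectra over artifact-free
  epochs per state (missing, not zero, when a state has none);
  NREM SWA averaged in ZT-aligned 2-h bins, NaN where no artifact-free
  NREM epoch exists (e.g. during enforced waking).  Absolute µV² are
  reported; normalisation to each recording's mean total power is an
  opt-in flag since reporting conventions vary.

## Vigilance scoring

Rule cascade per epoch: EMG RMS above its threshold → WAKE; else
theta/delta ratio above its threshold → REM; else NREM.  Thresholds
are set per recording by Otsu's criterion on the log distributions
(EMG over all epochs; ratio over non-wake epochs); when a distribution
shows no bimodal separation (< 1 pooled-SD between class means) the
scorer warns and falls back to fixed quantiles (0.5 for EMG, 0.85 for
the ratio).  A 3-epoch majority vote removes single-epoch flicker
(disable-able).  Scoring is deterministic.  Accuracy (≥ 90%, typically
≈ 99% on defaults) is defined against simulated ground truth only —
no claim is made about agreement with human visual scoring of real
recordings.

Aggregation: state percentages per ZT-aligned 2/6/12/24-h bin
(half-open bins, trailing partial bins rejected unless allowed);
interval labels L1/D1 (baseline light/dark) and L2/D2 (post-SD);
waking peak = midpoint of the maximal 2-h bin in the dark/dim half,
ties to the earliest bin; day–night amplitude = dark mean − light
mean per state; recovery-vs-baseline comparisons pair bins at equal
clock time.

## Statistics

Fixed-effects ANOVA via OLS with Type-II sums of squares (robust to
the unbalanced 5-vs-9 group sizes; the source convention is unstated).
Unpaired comparisons default to Welch's t (pooled-variance Student
available by flag); paired comparisons use the paired t.  Bonferroni
adjustment `p_adj = min(1, m·p)` with the family size `m` declared by
the comparison plan.  A summary-statistics one-way ANOVA
(means/SDs/ns) supports printed-table inputs.  OLS regression (slope,
intercept, SEs, R²) serves the waking-peak-delay vs exposure-index
fit, with the exposure index coded 1–4 for 0/1/7/30 days of exposure
rather than raw day counts.

## Problem sizes and determinism

Default analyses use 15-day activity traces (21,600 one-minute bins)
and 1–2 day recordings (21,600 epochs/day); the test suite and the
acceptance script run ensembles of 5–10 seeds per condition, which
keeps every stage's Monte-Carlo error well inside the asserted
tolerances while the whole suite completes in about a minute.  All
generators are bit-reproducible given their seed; per-animal seeds are
derived arithmetically from a master seed.

## Known limitations

* The periodogram strength statistic is implementation-specific;
  published absolute strengths (0.21/0.14/0.11) are matched in
  ordering, and incidentally in control magnitude, but not contracted.
* The scorer's adaptive thresholds assume bimodal EMG and ratio
  distributions; heavily disrupted recordings fall back to quantiles.
* The homeostat has no REM pressure, no sub-staging of NREM, and no
  circadian modulation of REM propensity beyond the transition
  matrices.
* Synthetic EEG epochs are spectrally exact but phase-incoherent
  across epochs; metrics sensitive to long-range EEG phase structure
  are out of scope.
* DFA is first order with non-overlapping windows; multifractal and
  higher-order variants are out of scope.
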