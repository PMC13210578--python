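# Methods

This note documents the models, estimators, defaults and numerical choices
behind `muscleox`, and what the synthetic-data validation does and does not
establish about real recordings.

## Data model and conventions

All signals are `SampledTrace` objects: uniformly sampled values with a rate,
a start time and NaN for missing samples. Time is in seconds from recording
start and every windowed statistic uses half-open windows `[start, end)`, so a
sample on a boundary belongs to exactly one of two adjacent windows. CSV input
is mapped onto a uniform grid whose step is the median inter-sample interval
(tolerating 1 % jitter); gaps become runs of NaN. This makes "insert missing
markers for dropouts" a property of reading, not of each downstream analysis.

## Signal-quality control

Published descriptions of these protocols exclude recordings when "the signal
was lost" without stating a criterion, which is usually adjudicated visually.
We operationalize it: a sample is *lost* if missing or outside the physical
0–100 % SmO₂ band; a loss event is a maximal lost run longer than `max_gap_s`
(default 2 s — long enough to span several beats of true signal, short enough
that interpolation across it would be untrustworthy); a recording is excluded
when a loss event intersects the metric's analysis window (for the cuff test,
the post-release recovery window). All three pieces are configurable, and
`detect_signal_loss` reports the segments so exclusions are auditable.

## SmO₂ kinetics

**Occlusion slope.** OLS slope of SmO₂ against time over the full occlusion,
requiring ≥ 30 s of observed data. OLS on the raw 10 Hz samples is exactly the
"linear slope" a chart package computes and is invariant to time-origin shifts.

**Increment and time constant.** The recovery increment is
`I = target − SmO₂(onset)`; the time constant is read as the time of the first
sample at or after onset reaching `SmO₂(onset) + 0.63·I`. This is a threshold
crossing, not an exponential fit: it is defined for any monotone-ish recovery,
and for a true mono-exponential it returns `−τ_exp ln 0.37 ≈ 0.994 τ_exp`
quantized up to one sample period (the grid-bracket property tested in the
suite). The target level is the maximum SmO₂ inside a post-release search
window for the occlusion test (default 60 s — the hyperemic peak in these
protocols arrives well inside a minute; configurable) and the pre-test
baseline for the exercise test.

*Noise robustness.* A raw single-sample maximum over a 600-sample window is
biased upward by roughly three noise SDs, which inflates `I`, raises the 63 %
threshold, and biases τ̂ upward by more than the estimator's own grid error.
The bundle analyzers therefore apply a centered 0.5 s moving average *inside*
the increment/τ computation only (start value, peak target, crossing), default
`reox_smooth_s=0.5`, settable to 0 for strictly raw analysis. On noiseless
mono-exponentials the smoothing shifts the continuous crossing by
`τ·ln(sinh(h/τ)/(h/τ))` with `h = 0.25 s` — under a millisecond for
physiological τ — so the grid-bracket property is preserved, while at noise
SD 0.5 % the median relative τ̂ error drops to ~3–4 % (the suite requires
< 10 % over 200 seeded traces). Slopes, window means and Rep 10 s endpoints
always use raw samples.

**Rep 10 s.** Default is the endpoint-averaged difference quotient
`(v₁ − v₀)/10` with 0.5 s endpoint windows ending at onset and onset + 10 s:
a "rate over 10 s" reads most naturally as a difference quotient, and the
0.5 s averaging suppresses single-sample noise without touching the 10 s
span; it leaves linear signals' slopes exactly invariant. A 10 s OLS slope
mode is exposed (`mode="slope"`) since either convention is defensible.

**Derived rate.** `R = I/τ` is stored from the same `I` and `τ` fields, so the
identity holds to machine precision per recording. Note that a *group mean* of
per-subject ratios is not the ratio of group means; the package never forms
the latter.

**Pre-recovery SmO₂** is the mean over the last 10 s of exercise (default,
configurable): long enough to average noise, short enough not to dilute the
steady-state value with the onset transient.

**Desaturation AUC** (trapezoidal area between the baseline level and the
signal during occlusion) is provided as an optional descriptor but is not part
of the validated metric set.

## Hemodynamics

Flow uses the standard conduit relation `Q = TAMV·π(d/2)²·60` (mL/min).
Diameter is held constant over a test unless a diameter series is supplied, in
which case its baseline-window mean is used — conduit-artery diameter change
over three minutes is second order relative to velocity change. Velocities are
assumed already angle-corrected at acquisition. Negative beat-mean velocities
are clamped to zero with a warning rather than propagated into negative flows.

Beats are segmented at prominence-filtered local minima of the velocity
waveform (minimum spacing 0.3 s, prominence ≥ 30 % of the pulse amplitude —
robust for half-sinusoid-like femoral waveforms and configurable for others).
Because a peak detector cannot mark an onset at the first array index, a full
leading beat (e.g. when the analysis window starts exactly at cuff release) is
recovered by extrapolating one median beat period backward. If the first
detected post-release beat starts more than 2 s after release, the metrics are
flagged `delayed_insonation`, since a fast-decaying hyperemic peak may have
been missed; a peak below baseline is flagged `no_hyperemia` rather than
suppressed.

The hyperemia readout — highest mean flow over three consecutive post-release
beats — is *by definition* below the instantaneous envelope peak when the
decay is fast (for a decay time constant of five beat periods the 3-beat mean
sits ~17 % below the envelope peak). Round-trip tests therefore compare
against the ground-truth 3-beat expectation the simulator records, and
against the configured envelope peak only under slow decay, where the two
coincide to within beat discretization.

## CPET reduction

VO₂max is the maximum over all rolling 30 s windows (sample-by-sample advance;
disjoint 30 s bins are available as an option), with HR_max taken as the HR
mean and PPO as the maximum commanded power within that same window, and
relative VO₂max as `abs·1000/mass`. A VO₂ plateau flag (|slope| in the peak
window < 0.005 L·min⁻¹·s⁻¹, i.e. < 0.15 L/min across the window) is reported
but never blocks output — plateau verification is a judgement criterion, not a
computation with a unique definition. Steady-state summaries are last-30 s
means.

## Cohort statistics

Paired t-tests on post − pre differences with exact degenerate handling
(identical vectors → t = 0, p = 1; a constant nonzero shift → p = 0 with a
`degenerate` flag rather than a division error). Cohen's d defaults to the
summary-statistics form `(m_post − m_pre)/√((sd_pre² + sd_post²)/2)` — the
variant consistent with published effect sizes recomputable from printed
means/SDs in this literature — with the change-score variant
(`mean_diff/sd_diff`) exposed because some published values are only
consistent with that form. Correlations of changes use Pearson's r with the
t-based two-sided p. The outlier-sensitivity rerun returns the full-sample and
reduced-sample correlations *together with the excluded ids*, so exclusion is
always explicit. No multiple-testing correction is applied; p-values are raw.
Missing pairs are deleted listwise per metric with retained and dropped counts
reported.

## Synthetic-data generators

Each generator is a pure function of its config and seed (bit-reproducible)
and returns the ground truth alongside the signals.

- **Cuff trace**: 60 s plateau → linear desaturation (default −0.06 %/s for
  180 s from 65 %) → mono-exponential rise (τ = 10 s) toward baseline + 5 %
  overshoot → once the rise is 99 % complete, exponential relaxation of the
  overshoot (60 s) back to baseline. The piecewise construction keeps the
  recovery an exact mono-exponential so estimator properties are testable in
  closed form.
- **SSE trace**: plateau at 68 % → exponential drop of 7.8 % (onset τ 25 s)
  over 180 s of exercise → mono-exponential recovery (τ = 14.5 s).
- **Doppler**: half-sinusoid velocity beats on a regular 60/HR grid, each
  scaled so beat TAMV × lumen area × 60 equals the envelope flow at the beat
  onset; envelope 70 mL/min at baseline, ~0 during occlusion, stepping to
  1400 mL/min at release (one beat onset is aligned exactly to release) and
  decaying with τ = 30 s.
- **Cohort**: per metric, bivariate-normal pre/post pairs with specified
  means, SDs, within-subject correlation and standardized effect (post − pre
  in pooled-SD units); perfect correlation degenerates correctly to a
  constant shift.
- **CPET**: 100 W + 5 W/15 s ramp with VO₂ saturating at VO₂max and a held
  plateau.

Noise is additive i.i.d. Gaussian (default SD 0.5 % SmO₂, matching the visual
noise band of consumer NIRS sensors; 0.5 cm/s on velocity), with optional
per-sample dropout. The generators deliberately do **not** model O₂ transport
physiology, motion artifact, adipose-layer attenuation, probe repositioning,
beat-to-beat HR variability or diameter pulsatility. Passing round-trip tests
therefore demonstrates that the estimators recover the parameters of the
stated signal model under realistic noise — not that the metrics are accurate
on arbitrary field recordings.

The end-to-end study simulator (`muscleox.study`) plants training adaptations
as mean within-subject parameter shifts (VO₂max +0.43 L/min, occlusion slope
−0.012 %/s, cuff τ −3 s, hyperemic peak +241 mL/min, exercise SmO₂ drop
−3.5 %, SSE recovery τ −2.3 s, …) scaled by a per-subject response factor
~ N(1, 0.5), so most subjects adapt and a few regress. At n = 16 the signs of
all reported mean differences match the planted directions with overwhelming
probability, which the acceptance suite checks at a fixed seed.

## Problem sizes and runtime

Default simulated recordings are 420 s at 10 Hz (SmO₂) and 100 Hz (velocity);
the demo study is 16 subjects × 2 sessions × 4 recordings, the noisy-recovery
validation uses 200 seeded traces, and the type-I calibration 1000 null
cohorts of n = 16 — sizes chosen so the entire suite completes in seconds
while keeping Monte-Carlo error well inside the asserted bands.

## Known limitations

- The 63 % threshold-crossing τ is biased for markedly non-exponential
  recoveries (it reports the 63 % crossing time, which is then the honest
  summary, but not a model parameter).
- Beat segmentation assumes reasonably clean pulsatile waveforms; heavily
  damped or irregular-rhythm recordings should be inspected via the returned
  beat series.
- The pooled-SD Cohen's d treats conditions as exchangeable summaries and
  ignores the pre/post correlation; the change-score variant is provided but
  the two are not interchangeable when comparing against published values.
- QC thresholds (2 s loss runs, 0–100 % validity band) are pragmatic defaults,
  not clinically validated criteria.
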