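# Methods

## The exposure model

Personal exposure to traffic pollution is treated as the product of what
is in the air and how much of that air is breathed.  For one walker on
one journey, sampled at 1 Hz, each sample i receives the index

    E_i = (NO2_i / max NO2) · (D_i / max D) · (R_i / max R)

where NO2 is ambient nitrogen-dioxide concentration (the standard marker
for traffic pollution), D is relative nasal-airflow depth, R is breathing
rate in breaths/min, and each maximum is taken over the journey's valid
(non-gap) samples.  The index lives on [0, 1]: 0 whenever any factor is
0, and 1 only at a sample where all three factors are simultaneously at
their journey maxima.  The model is deliberately linear: with the maxima
held fixed, doubling any one factor at a sample doubles that sample's
exposure, and rescaling an entire factor series (a sensor gain change)
changes nothing, because the normalisation absorbs it.

The maxima are per journey, never pooled across journeys or people.  The
index is a relative snapshot of one person's experience of one route at
one time; exposure values from different journeys are not comparable and
must not be aggregated to characterise places.  This is a modelling
stance, not an implementation shortcut: breathing response dominates the
index in ways that are specific to the person, route direction and day.

Non-goals: inhaled dose in physical units (µg), health-outcome inference,
and nonlinear exposure–response forms are all outside scope.

## Breath metrics from the thermocouple signal

The nasal sensor is a thermocouple resistor whose reading rises with each
exhalation, giving one peak per breath over a slowly drifting baseline.
The raw trace is detrended with a zero-phase 2nd-order Butterworth
band-pass (0.05–1.2 Hz; plain high-pass when the sampling rate is too low
for the upper leg).  The passband brackets human breathing — 6 to 72
breaths/min — so drift and high-frequency sensor noise are removed
without attenuating the breath oscillation itself.  A rolling-median
baseline was evaluated and rejected: a median window spanning a
non-integer number of breath cycles partially tracks the oscillation,
biasing per-breath amplitude by up to ~30 % at 10 breaths/min, while the
band-pass keeps the noise-free bias below 1 % across 10–25 breaths/min.

Breaths are then peaks of the detrended signal with a prominence floor
and a minimum separation (`min_period_s`, default 1.0 s ≈ 60 breaths/min
ceiling).  The default prominence is adaptive — 0.3 × the 95th percentile
of the detrended magnitude — so detection, and hence the rate, is
invariant to rescaling the raw signal; an absolute floor in raw units can
be passed instead.  Each breath's amplitude is its peak height above the
(zero-mean) detrended baseline; depth is therefore relative — the sensor
is uncalibrated and only ratios of depth are meaningful, which is all the
index needs.

Per-second metrics use a trailing (causal) window, default `window_s` =
30 s, at least twice the longest plausible breath period: rate is
60 × (breaths in window) / window, depth is the mean amplitude of those
breaths, both 0 when the window holds no breath.  Causal windows mean the
metrics are computable in a streaming setting; they also mean the
estimates lag the physiology by up to the window length, and the rate is
quantised in steps of 60/window_s breaths/min.

## NO₂: calibrated and relative modes

Chamber calibration of the metal-oxide sensor against known dilutions of
a certified gas standard yields (concentration, raw reading) pairs.  The
curve through them is a monotone piecewise-linear interpolant — no
parametric form is assumed because such curves drift over time — with
linear extrapolation from the terminal segments, clamped at 0 ppm.  The
monotone sense (raw rising or falling with concentration) is inferred
from the points.  Each curve carries a `fitted_at` stamp.

The index itself needs no calibration: `relative_concentration` min-max
scales a journey's raw readings to [0, 1], which is invariant to any
positive affine sensor response.  A constant raw series maps to all
zeros with a warning ("no relative variation observed") rather than an
error.  Cross-sensitivity to temperature/humidity and drift modelling are
out of scope.

## Track fusion

The GPS, gas and airflow devices are independent units with
unsynchronised clocks, so fusion is a nearest-in-time join with tolerance
(`max_gap_s`, default 3 s) onto a regular grid anchored at the log's
first timestamp (default 1 s interval), rather than resampling filters.
Positions are interpolated linearly between bracketing fixes — journeys
are walking-scale, where great-circle corrections are far below GPS
error.  A grid sample whose bracketing fix interval (or nearest channel
sample) exceeds the tolerance is gap-flagged but retained, so exported
maps show where data are missing; gap samples carry no exposure value and
are excluded from the journey maxima.

## The journey simulator

No hardware is needed to exercise the pipeline: the simulator generates a
ground-truthed walk and emits it in the logger CSV dialect.  A scenario
is a contiguous chain of polyline segments, each labelled with one of
four zones (traffic_control, steep_climb, residential, park) and a
gradient, plus NO₂ "hotspots".  The walker advances at constant speed
(default 1.4 m/s).

**NO₂ field** — base level plus a sum of isotropic Gaussian kernels, one
per hotspot.  Roadside NO₂ falls off within tens of metres of the source;
a kernel is the simplest field with that property.  Defaults: base
0.010 ppm, junction hotspots 0.040–0.045 ppm at σ = 30 m — i.e. roughly
10 ppb background rising to ~50 ppb at a congested signalised junction,
ordinary urban values.

**Breathing response** — depth rises with first-order lag (τ = 20 s)
toward double its resting value while on the climb; frequency rises only
part-way (75 % of the rest→ceiling range: breath is managed during
effort) and then surges quickly (τ = 5 s, for 15 s) to its ceiling of 28
breaths/min when the climb ends — the post-exertion hyperpnea that puts
the frequency maximum *after* the climb.  Both decay exponentially back
to rest, frequency with a 90 s half-life (recovery from a 200 m steep
climb takes minutes) and depth with a 15 s half-life (tidal depth
normalises much faster than frequency).  The separate half-lives are what
make the journey's characteristic pattern — depth maximal during the
climb, frequency maximal after it — visible through the causal windowed
estimators, not only in the ground truth.

**Waveform** — the airflow channel is a quasi-sinusoid at 25 Hz whose
instantaneous period and peak amplitude track the true rate and depth,
plus a slow baseline drift (0.3 raw units over a 5-minute period,
mimicking thermocouple temperature drift) and Gaussian noise (σ = 0.02
raw units against a resting amplitude of 1.0).  The NO₂ channel is an
affine sensor response (offset 1000, 20 000 raw units/ppm) plus Gaussian
noise (σ = 5 raw units ≈ 0.25 ppb).  All randomness flows from a single
seed through named child streams; identical seed and parameters give
byte-identical files.

**Default route** — a ~1.2 km loop: a flat 400 m traffic-control street
with two junction hotspots, a 200 m climb at 10 % grade, a 400 m
residential street, and a park descent back to the start.  A broad,
low-amplitude kernel (0.028 ppm, σ = 140 m) over the residential area
models its distributed light traffic.  The geometry and defaults were
chosen so the route reproduces, by construction, the qualitative spatial
pattern the pipeline is meant to reveal: NO₂ maximal at a junction
hotspot, depth maximal on the climb, rate maximal just after it, and —
because elevated post-climb breathing coincides with moderate residential
NO₂ — mean exposure over the residential segment exceeding the mean over
the traffic-control zone even though its NO₂ is far lower.

What the simulator does **not** emulate: GPS position error and urban
multipath, NO₂ sensor drift and cross-sensitivities, gusts and
meteorology, irregular human breathing (sighs, talking, breath-holds),
and clock skew between devices.  Passing tests therefore demonstrate that
the algorithms recover a known signal under idealised-but-noisy
conditions, not that field data from low-cost hardware will be this
clean.

## Numerical and edge-case choices

- Grid construction: `floor((t_last − t_first)/interval) + 1` points,
  anchored at the first timestamp (a 1e−9 s slack absorbs float error).
- Banding: equal-width bins on [0, 1], default 5, labelled
  "lowest", "band 2", …, "highest"; boundary values go to the upper bin
  except 1.0, which stays in the top bin.
- Degenerate journey maxima (a component identically 0, e.g. no breaths
  detected): exposure is 0 everywhere with a warning, not an error.
- Constant airflow traces produce zero breath events; a post-filter
  residue floor (1e−9 of the signal span) keeps numerically flat signals
  from producing spurious events.
- Lenient CSV parsing skips malformed rows and rows breaking timestamp
  order, reporting a count; strict mode fails on the first offence.
  Floats are written with shortest round-trip precision and re-parsed
  exactly.
- Problem sizes: the packaged route is 858 s at 1 Hz with a 25 Hz
  airflow waveform (~21 000 samples); a full simulate→process cycle runs
  in about two seconds on one core.

## Known limitations

- The trailing window delays and smooths breath metrics; transient
  physiology shorter than the window is attenuated.
- The rate estimator is quantised (2 breaths/min steps at the default
  window); comparisons finer than that are meaningless.
- Min-max NO₂ normalisation is journey-relative: a journey that never
  leaves clean air will still span [0, 1] in its relative series.
- Linear position interpolation ignores GPS error entirely; there is no
  map-matching or filtering.
- The exposure model's linearity is an assumption, not a validated
  dose–response relationship.
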