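# Methods

## The recognition problem

A single body-worn 3-axis accelerometer (ear, chest, upper arm or wrist)
records a person performing repetitive exercises — running, walking,
jumping, push-ups, sit-ups. The task is to cut the stream into single
motions, name each motion, and count repetitions per exercise, using **one
pre-recorded example motion per exercise** as the entire reference set. No
model is trained; recognition is nearest-template matching under dynamic
time warping (DTW), which makes the method deployable on a new user or a
new device position after recording five (or seven, see below) short
template motions.

## Pipeline

1. **Magnitude.** The combined magnitude `m[k] = sqrt(x² + y² + z²)` (in
   g) removes dependence on device orientation. The cost is that motions
   differing only in direction become harder to distinguish; the
   classifier therefore operates on the raw 3-axis segments, and only the
   *segmentation* runs on the magnitude.
2. **Short-term energy.** A centered moving average (default 1.0 s)
   estimates the quasi-static baseline — dominated by the 1 g gravity
   offset — and is subtracted; the squared deviation is then averaged over
   a centered window (default 0.25 s, reflect-padded). The result is a
   non-negative envelope with one hump per motion burst.
3. **Peak detection.** A sample is a peak iff it is the *strict* maximum
   of its centered 0.25 s window. 0.25 s is chosen so that even the
   fastest running cadence (just under four steps per second) puts at most
   one step per window. Ties (plateaus) never qualify — deterministic, and
   measure-zero on real signals. Peaks within half a window of the stream
   ends are suppressed (no full window exists). Two optional height
   floors exist, both off by default: an absolute energy `min_height`
   (g²) and `min_height_frac`, a fraction of the envelope's global
   maximum. With both off, smoothing alone suppresses small ripples, so
   long quiet stretches *will* yield low-level noise peaks; batch
   evaluations in this package use `min_height_frac = 0.05` on
   single-exercise records and `min_height = 0.01 g²` on mixed circuits
   (a global fraction mis-scales when one loud exercise dominates the
   maximum).
4. **Segmentation.** The raw 3-axis data between consecutive peaks is one
   candidate motion. Candidates outside [80, 2000] ms are discarded —
   bounds chosen to bracket every published per-exercise segment-length
   range (96–1680 ms across positions) without admitting degenerate
   double-peaks or rest gaps.
5. **Classification.** Unnormalized DTW over the 3-vectors, Euclidean
   per-cell cost, no warping window, no path-length division:
   `D[i,j] = ||s_i − t_j|| + min(D[i−1,j], D[i,j−1], D[i−1,j−1])`. The
   argmin template class wins; ties break by the canonical registry order
   (running, walking, jumping, push-up, sit-up; right before left). A
   query whose sampling rate differs from the template's is linearly
   resampled; differing *lengths* are DTW's own job. An optional
   length-normalized mode (divide by `n + m`) exists behind a flag for
   experimentation and is off by default.
6. **Counting.** Every accepted classification increments its exercise's
   counter; the sum of counters equals the number of accepted segments by
   construction.

### Templates and wear positions

Ear- and chest-mounted sensors cannot distinguish a right step from a left
step, so their registries hold **five** templates. Arm and wrist motion
differs between strides, so those registries split running and walking
into right/left variants — **seven** templates — merged back to five
exercise labels for scoring.

### The sit-up problem

A sit-up's circular trunk motion migrates the dominant axis within one
repetition, producing **three** energy peaks per cycle, so segmentation
cuts each sit-up into three sub-segments. The sit-up template is the
"wake-up" (trunk-raising) sub-segment. By default every sub-segment is
still classified and counted — the over-count is visible and measurable.
The documented mitigation is the optional rejection threshold τ (DTW
distance per query sample): sub-segments other than the wake-up resemble
no template and score far above it. On noiseless synthetic data the
margin is wide (wake-up ≤ 0.1 g/sample, others ≥ 0.25 g/sample at every
position) and τ = 0.2 separates them exactly; on noisy data the matched
score floor rises with the noise level and τ should be recalibrated.

## Synthetic data generator

The generator exists because the study conditions it emulates — five
exercises at four positions — have no shareable recordings. It renders
each exercise as an amplitude-modulated oscillation in a body frame:
a periodic unimodal envelope (raised-cosine powers, or an asymmetric
ramp for jumping) times a sinusoidal carrier, with per-cycle tempo and
amplitude jitter (coefficients of variation) and white Gaussian noise.
Cycle counts follow the emulated protocol: >20 steps of each gait,
~10 repetitions of the others. Default per-exercise parameters:

| exercise | period (s) | peak amplitude (g, x/y/z) | tempo CV | shape |
|----------|-----------:|---------------------------|---------:|-------|
| running  | 0.35 | 0.5 / 0.8 / 2.2 | 0.08 | sharp impulse train |
| walking  | 0.60 | 0.3 / 0.5 / 0.9 | 0.08 | smooth hump |
| jumping  | 0.70 | 0.4 / 0.6 / 2.8 | 0.08 | fast rise, slow decay |
| push-up  | 1.10 | 0.3 / 0.9 / 0.5 | 0.15 | slow smooth hump |
| sit-up   | 0.90 | 0.15 / 1.2 / 1.2 | 0.10 | three bumps, axis rotation |

Each base period lies inside the corresponding published chest
segment-length range; the push-up spec (1.1 s, CV 0.15) puts ≥ 99% of
simulated cycles inside the published 558–1673 ms chest range. Amplitude
jitter is 0.1 and the default noise floor 0.05 g everywhere.

Three numerical choices keep the envelope's one-peak-per-cycle contract
exact rather than approximate:

* carrier frequencies are chosen so the 0.25 s energy window is an integer
  multiple of the squared-carrier period — the moving average then cancels
  the carrier ripple exactly at the base tempo, leaving a unimodal energy
  hump per cycle (sit-up: three);
* envelope peak phases avoid exact half-sample symmetry, which would
  produce tied neighboring samples that the strict-maximum rule rejects;
* each bout starts and ends with a half-cycle cosine taper into quiet
  standing, so bout edges do not step the envelope.

**Position transforms.** Each wear position applies a fixed orthonormal
rotation, per-axis attenuation (ear 0.5 — head motion is mechanically
filtered; arm 0.8; wrist 0.7), extra sensor noise at the loosely coupled
ear (+0.02 g), and — during gait at arm/wrist — an arm-swing component
with a right/left amplitude asymmetry (device worn on the left side).
The swing is injected along the sensor direction orthogonal to gravity:
it shapes the 3-axis waveform (making strides side-separable for DTW)
without perturbing the magnitude envelope that segmentation relies on.
Gravity (1 g along the transformed vertical) is always present. All four
positions of a circuit render the *same* cycle timing; only sensor noise
is redrawn.

**Ground truth** records every cycle's span, label, stride side, analytic
energy-peak sample, and *motion window* — the peak-to-peak span of the
canonical motion (for sit-ups, the wake-up span). Randomness comes
exclusively from NumPy's seeded PCG64 generator; equal seeds give
bit-identical output.

**What the generator does not emulate:** soft-tissue artifacts, sensor
drift and saturation, orientation changes during a bout, inter-subject
variability beyond amplitude/tempo jitter, and non-exercise confounders
(gestures, vehicle vibration). Tests passing on this generator show the
pipeline's mechanics are correct under the stated signal model, not that
the published accuracy figures transfer to real recordings.

## Evaluation protocols

**Segmentation recall** — a ground-truth cycle counts as recovered when at
least one segment midpoint falls inside it (each cycle at most once,
ratio capped at 1). The recall table is position × exercise with a
per-position total weighted by true repetition counts.

**Random-template validation** — from a pool of *correctly segmented*
labeled motions (each segment must cover ≥ 60% of its cycle's motion
window; for sit-ups only wake-up spans qualify), draw one template per
class uniformly at random, classify all remaining pool segments, record
micro accuracy (right/left merged before the correctness check) and
per-class F1; repeat (default 50 iterations) and report mean, sample
(n−1) SD, max and min. A drawn template is never in its iteration's test
set. A class never predicted in an iteration scores F1 = 0 for that
iteration and is included in the mean. Micro (segment-weighted) accuracy
was chosen over macro because per-class totals differ by design (steps
vs. repetitions); the per-class F1 columns carry the class-resolved
signal.

At the defaults (0.05 g noise), 50-iteration validation on a chest pool
of ~76 segments yields mean accuracy ≈ 0.97, with the ear position worst
(≈ 0.92) — the attenuated, noisier ear signal degrades template quality,
mirroring the ordering reported for real recordings, though the synthetic
arm/wrist positions are cleaner than their real counterparts.

## Numerical and engineering notes

* Durations are converted to samples by rounding, and windows forced odd
  so "centered" is exact; the energy and peak windows default to 0.25 s,
  the detrend window to 1.0 s (it must not be shorter than the energy
  window).
* The DTW inner loop is JIT-compiled with numba (two-row rolling buffer);
  a pure-Python fallback produces identical results. The cost matrix is
  vectorized NumPy.
* Boundary effects: n detected peaks bound n − 1 segments, so a bout of
  R repetitions yields at most R − 1 segments; counts are reported as-is
  and compared to truth within ±1 in the noiseless tests. In mixed
  circuits each bout additionally risks its first/last cycle (tapered
  onset/offset) and, under noise, an occasional split cycle, so replayed
  circuit counts can fall up to 2 short per exercise.
* Template extraction in the synthetic bank runs the *pipeline's own*
  peak detector on a noiseless periodic rendering and slices the central
  inter-peak span — exactly how a user would record a template — so a
  noiseless stream matches its template with DTW distance ~0.
* Signal CSVs are written with `%.17g` and read with pandas'
  `round_trip` float parser, giving bit-exact round-trips; template
  stores are versioned JSON whose floats round-trip exactly by Python's
  shortest-repr encoding.

## Known limitations

* The rejection threshold τ is a per-query-sample distance, so it is
  noise- and amplitude-dependent; there is no automatic calibration.
* Plateau (tied) envelope maxima are never peaks; a genuinely flat-topped
  burst would be missed. Real noise makes exact ties measure-zero.
* Segmentation of mixed streams relies on an energy floor to ignore rest
  gaps; with all floors off, rest noise produces spurious low segments
  (documented, deterministic given the seed).
* Batch processing only: the architecture permits a streaming wrapper
  (the peak rule needs half a window of lookahead), but none is provided.
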