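# Methods

`synkin` analyzes repeated upper-limb motor tasks — the motivating case is
the overhead volleyball set, performed in nine variants of ten repetitions
each — recorded with two synchronized streams per session: six joint-angle
traces at 100 Hz (shoulder flexion-extension, abduction-adduction and
internal-external rotation; elbow flexion-extension and
pronation-supination; wrist flexion-extension, all in degrees) and raw
surface EMG of 16 upper-limb and trunk muscles at 2000 Hz.

## Repetition segmentation

Events are detected on the elbow flexion-extension angle. The trace is
low-pass filtered (Butterworth, 3 Hz cutoff, order 4, applied zero-phase)
and differentiated with central differences. The peak threshold is a
fraction (default 0.25, usable range roughly 0.20–0.30 per set type) of the
maximum absolute derivative over the whole recording; derivative maxima
above it are candidate flexion peaks and minima below its negative are
candidate extension valleys, both thinned so that peaks closer than
`min_event_separation_s` (default 0.5 s, safe under the protocol's 2 s
inter-repetition rest) keep only the largest. Each retained maximum is
paired with the first following retained minimum; the onset is the last
derivative zero-crossing before the maximum and the offset the first after
the minimum. Events lacking a flanking crossing are clamped to the trace
ends and flagged, never dropped, so repetition counts stay auditable.

Two numerical choices matter here:

* **Zero-phase filtering.** Applying the filter forward and backward
  removes phase lag (a causal 3 Hz filter would delay every detected onset
  by tens of milliseconds) at the cost of doubling the effective
  attenuation. All pipeline filters follow this convention.
* **Dead-band zero-crossings.** A zero-phase IIR filter pre-rings: the
  filtered angle undershoots slightly *before* a movement begins, which
  puts a strict sign-change crossing 50–80 ms early even on noise-free
  data. Crossings are therefore detected with a small dead-band — samples
  within `zero_tol_fraction` (default 0.03) of the derivative amplitude
  count as zero; the onset is the last sample at or below the band before
  the peak, the offset the first back inside it after the valley. At
  tolerance 0 this reduces to the strict sign-change rule. With the default
  the recovery error on simulated sessions is within ±30 ms.

## Joint-angle summaries

For analysis all six channels are low-pass filtered at 3 Hz (zero-phase,
order 4). Within each set type the repetition with the longest duration
fixes the profile length; every other repetition is linearly resampled to
it, and the per-sample mean and sample standard deviation (ddof = 1) across
repetitions form the mean profile. Durations therefore remain comparable
across set types while repetitions align within a type. Range of motion is
max minus min of each filtered repetition trace, summarized per (set type,
degree of freedom) by median and quartiles (linear interpolation between
order statistics). Linear interpolation is used for all resampling; spline
interpolation is deliberately out of scope.

## EMG envelopes and the synergy model

Per channel: 10 Hz high-pass (Butterworth, order 5, zero-phase) on the raw
signal, full-wave rectification, 5 Hz low-pass (same family) on the
rectified signal; residual negative ringing is clamped to zero. Each
repetition contributes the window from 0.25 s before its onset to 0.25 s
after its offset — the padding captures the EMG activity that precedes and
trails the kinematic event — resampled per channel to T = 100 samples. The
T samples span the padded window (not onset-to-offset alone), so the
padded activity actually survives into the epoch. Epochs are concatenated
in chronological order into an M × (K·T·N) matrix (M = 16 muscles, K set
types, N repetitions) and every muscle row is divided by its maximum over
all trials; a muscle with zero envelope everywhere is reported as a dead
channel rather than rescaled.

The spatial synergy model factorizes the matrix V ≈ W C with W (M × S)
holding non-negative spatial synergy vectors and C (S × L) non-negative
activation coefficients. Fitting uses multiplicative updates for the
squared Euclidean loss — the standard algorithm in the synergy literature —
with 20 random restarts per order; each restart draws its initialization
from a seed spawned deterministically from the master seed (all restart
seeds are recorded in the model), iterates until the relative change of
the squared error falls below 1e-6 or 1000 iterations, and the restart
with the lowest error wins. The update loop runs in single precision for
speed (which also bounds the resolution at which the convergence test can
operate; the iteration cap covers the remainder) and the factors are
returned in double precision. Goodness of fit is R² = 1 − SSE/SST with
SST taken about the per-muscle mean vector (a vector, not a global scalar).
Orders 1..M are always fitted — the R²-versus-order curve is itself a
result — and the selected order is the smallest with best-restart
R² ≥ 0.80, or M with a warning. After fitting, each spatial vector is
scaled to unit Euclidean norm and its coefficient row by the reciprocal,
leaving W C unchanged to within 1e-10.

## Test–retest statistics

Sessions are compared at a common synergy order (the pipeline refuses to
compare sessions whose automatic selection disagrees; fix a common order
instead). Spatial vectors are paired by the bijective assignment that
maximizes total cosine similarity, solved exactly with the Hungarian
algorithm — a greedy pairing would be order-dependent. Temporal
consistency is the Pearson correlation (two-sided p from the t transform,
n − 2 df) between session-mean activation curves of matched synergies, per
set type; both curves are resampled to 100 samples first since sessions may
differ in duration. Kinematic repeatability per set type and DOF uses the
same resampled session-mean curves: Pearson r plus ICC(3,k) — the two-way
mixed-model intraclass correlation for consistency of average measures —
with the 100 time samples as targets and the two sessions as raters,
ICC = (BMS − EMS)/BMS from the two-way ANOVA decomposition and the 95 % CI
from the Shrout–Fleiss F bounds. Consistency bands: excellent (> 0.90),
good (0.75–0.90], moderate (0.50–0.75], plus a "poor" band (≤ 0.50) added
below the three conventional ones for completeness. Consistency ICC is
invariant to a constant offset between sessions (sensor re-placement
shifts a whole curve without changing its shape), which is exactly why it
is the right coefficient here. No multiple-testing correction is applied;
p-values are reported at machine precision.

## Synthetic sessions

No public recordings of this protocol exist, so the generator produces
sessions with known ground truth; its defaults are the study conditions
every end-to-end test runs under: 9 set types × 10 repetitions, 16
muscles, T = 100, S = 5 synergies, 20 dB SNR, 2° angular variability.

**Kinematics.** Each set type has a 6-DOF template of raised-cosine
excursions with set-specific durations (1.5–3 s) and peak angles (shoulder
flexion-extension peaks 160–200°, i.e. ranges of roughly 150–190°; elbow
flexion peaks 95–105° over a 30° baseline). Repetitions sit on a timeline
with 2.5 s rest. Angular variability is a 1 Hz band-limited Gaussian
process scaled to `within_rep_noise_deg` (default 2°) and windowed by the
movement profile, plus an optional constant session offset emulating
sensor re-placement. The windowing reflects how sensor-derived joint
angles behave: essentially flat at rest, smoothly variable during
movement. Unwindowed white noise would be a sensor-noise model instead,
and its filtered sign-runs would make any zero-crossing onset rule
arbitrarily inaccurate — a genuine limitation of velocity-threshold
segmentation on noisy rest baselines that the windowed model deliberately
does not exercise.

**EMG.** The true envelope of each padded epoch is W_true · C_true:
sparse, largely muscle-group-disjoint spatial patterns (arm raise, final
push, wrist/ball handling, trunk stabilization, initiation) and truncated
Gaussian activation bumps whose centers follow the recruitment order
initiation → arm raise → wrist → stabilization → push, jittered per
repetition (SD 0.03 of the epoch) with per-set amplitude modulation (the
push synergy is barely recruited in the three middle-blocker variants and
the quick 'two' set to the opposite hitter, where the arms never reach
full extension). Per-synergy gains are balanced by a
fixed-point iteration so that, after the pipeline's per-muscle max
normalization, every synergy carries a comparable share of the EMG
variance. The envelope multiplies a band-limited (20–450 Hz) unit-variance
Gaussian carrier — standard surface-EMG phenomenology — and white sensor
noise is added at `snr_db` (power ratio of modulated carrier to noise).
Each epoch also receives an independent per-muscle amplitude gain
(`rep_gain_sd`, default 0.4, truncated at 0.2): surface-EMG amplitudes
fluctuate between repetitions with coefficients of variation of this
order, and this trial-to-trial variability is what keeps the
R²-versus-order curve realistic — without it the data are exactly rank S
up to small noise, every low order fits nearly perfectly, and an
R²-threshold order-selection rule becomes degenerate. Under the defaults
the best-restart R² reaches ≈ 0.77 at order 4 and ≈ 0.87 at order 5, so
the 0.80 rule selects the generative order with margin on both sides.

**What passing these tests does and does not show.** The generator
reproduces the structure of the protocol (dimensions, timing, synergy
recruitment, amplitude variability) but not everything about real
recordings: no electrode lift-off or motion artifacts, no fatigue drift,
no duration variability between repetitions of a set type, Gaussian rather
than heavy-tailed variability, and rest baselines that are exactly flat.
Recovery of the planted truth therefore validates the implementation and
the identifiability of the method under its stated assumptions, not its
robustness to every pathology of real surface EMG.

## Problem sizes and determinism

End-to-end tests run the full default session (16 × 9000 envelope matrix,
orders 1..16 × 20 restarts); unit tests use reduced configurations (1–2
set types, 2–3 repetitions) chosen to exercise the same code paths at a
fraction of the cost. Everything is reproducible bitwise from a single
master seed: the generator, the per-restart NMF seeds, and the pipeline
log that records seeds, filter settings, restart count and package
version for every run.

## Known limitations

* Segmentation assumes one flexion-extension cycle per repetition; tasks
  with multi-phasic elbow profiles would need a different pairing rule.
* The threshold base (maximum absolute derivative over the recording) is
  per-recording, so a single unusually fast repetition raises the bar for
  all others.
* Order selection by an R² threshold inherits that threshold's
  arbitrariness; cross-validation-based selection is out of scope.
* ICC(3,k) with time samples as targets treats samples as exchangeable
  targets and ignores their autocorrelation; its CI is therefore
  optimistic. This mirrors common practice for waveform consistency
  reporting.
* Single-subject, two-session designs only; no ICC(2,·)/ICC(1,·) designs.
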