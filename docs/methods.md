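# Methods

This note records the model, the numerical choices, and what the synthetic
benchmark does and does not demonstrate. Notation: Fs — sampling rate (Hz);
N_TS/N_TE/N_TD — titration-window start/end/duration (samples); K —
polynomial order. All indices are 0-based; intervals are half-open [s, e).

## Signal model and assumptions

A titration recording is a synchronized triple (NAVA_level, EAdi, Flow) on
a uniform grid, by default Fs = 62.5 Hz. The pipeline assumes:

* NAVA_level(n) is *noiseless* and piecewise linear — it is a machine
  setting, not a measurement. Equality with a fitted line is still tested
  with an absolute tolerance `line_tol = 1e-9` so that quantized exports do
  not fragment segments; on exactly-linear input the behaviour is identical
  to exact equality.
* EAdi(n) ≥ 0 (a rectified envelope in µV). Airway pressure is always
  reconstructed as Paw = NAVA_level·EAdi; a measured pressure channel, when
  present in a file, is carried for plotting only.
* Flow is in L/s with inspiration positive; tidal volumes are reported in
  litres. (Units are the package's convention; figures in the clinical
  literature often use mL.)
* Breath cycles last roughly 1–4 s, so inspiratory "mountains" of the
  smoothed EAdi envelope span several 240 ms frames.

## Stage-by-stage choices

**Line segmentation.** Greedy: anchor a line on two consecutive samples,
extend while the next sample lies on it within `line_tol`, restart on
violation. Segments partition the record; a trailing orphan sample becomes
a degenerate flat segment. Extension is evaluated in 256-sample chunks so
the cost stays linear for both long steps and fragmented traces.

**Segment classification.** The feature of segment ℓ is
[log|b_ℓ−b_{ℓ−1}|, log(e_ℓ−s_ℓ)]; both arguments are floored at exp(−27.6)
so repeated offsets stay finite. The first segment has no predecessor: it
is excluded from classification and inherits the label of the second
segment. The 2-component mixture is fitted by EM (full covariances,
k-means++ initialization, 10 restarts, covariance ridge 1e-6, fixed seed),
the titration component is the one with the smaller covariance
determinant, and segments are assigned by the larger component density.
If no segment lands in the titration class, or fewer than 4 segments
exist, the trace has no identifiable staircase. A consequence of the
inherit-from-second rule: a recording that *opens* with a long constant
directly followed by the staircase folds that constant into the window;
in practice (and in the simulator) the pre-titration phase contains the
reduction from the prior working assist to zero, which separates cleanly.

**Breath detection.** The causal moving average of order 40 keeps the
output nonnegative for nonnegative input; the first `order−1` samples
average the available prefix rather than zero-padding, avoiding a spurious
low-energy head. Frames are non-overlapping (each sample belongs to one
class); frame energies are floored at 1e-12 before the log; de of the
first frame is 0 by convention. In the 3-component mixture, expiration is
the component with the lowest mean energy; the other two (maximal and
minimal mean energy-derivative: rising and falling envelope slopes) form
the inspiration class. Class likelihoods sum the fitted *weighted*
component densities; the mixing weights are kept because EM returns
weighted components (for balanced classes the difference vanishes).

**Robust polynomial fits.** Degree-10 monomial fits over raw sample
indices (~1e5) are numerically singular, and the information functions add
quantities with different physical units. Both series are therefore
normalized before fitting: the predictor is mapped to t ∈ [0, 1] over the
span of the series and the response divided by max|y|. Derivatives are
taken in t, consistently for both series, so the decision argmin is
unaffected. The reweighting uses Tukey bisquare weights (tuning 4.685;
Huber available by config), scale = MAD/0.6745 of the residuals, at most
50 iterations, convergence when the weight vector moves < 1e-6. On clean
polynomial data the weights converge to 1 and the fit equals ordinary
least squares. The error series is √|fit − value| of the *normalized*
residuals, fitted at order K−1 by the same scheme — the square root is an
unusual residual transform but is applied exactly as specified.

**Fitted range and edge effects.** The plateau polynomials describe the
titration session located in step 1, not the whole recording: breaths
outside the window were recorded at unrelated operating points (e.g. the
pre-titration working assist) and would distort a global degree-10 fit.
However, a polynomial is least trustworthy at the very edges of its
domain — its derivative and the error polynomial oscillate there — and the
decision is evaluated across the entire window. The series is therefore
padded with up to ⌈B/K⌉ context breaths on each side (one ripple
half-wavelength of an order-K fit to B breaths), which moves the edge
region outside the window. Padding stops early at the first context
breath whose value is inconsistent (beyond 6 MAD-based SDs) with the
adjacent 25 in-window breaths, so context recorded at a clearly different
operating point is never included. Without this guard, planted-truth
benchmarks show the decision collapsing onto spurious zero-derivative
points at the first or last titration step.

**Decision.** The fuzzy prior is 1.5 − g(n)/max g with g Gaussian, mean
N_TS + N_TD/4 and spread N_TD/3. The defining description does not say
whether N_TD/3 is a variance or a standard deviation; it is interpreted as
a *standard deviation* (the scale-free reading — the prior's shape is then
independent of whether n counts samples, frames or seconds; the variance
reading would make the prior a near-delta notch at the quarter point).
The prior's mean is measured from the titration start, since the factor is
defined on the session. The decision curve is evaluated densely on every
window sample inside both information-function domains; ties at the
minimum break to the earliest sample (favouring lower assist, consistent
with the clinical "early after the transition" convention); NAVA_AL is the
recorded staircase value at the minimizing sample, without interpolation.

## The simulator

`SimulationParams` defaults encode the titration protocol: Fs = 62.5 Hz,
+0.1 cmH2O/µV every 20 s from 0 to 5 (50 steps), preceded by 20 s at a
prior working assist of 1.5 cmH2O/µV and 40 s unassisted (the protocol
reduces the level to zero and waits for sufficient EAdi before titrating),
and followed by 120 s at the chosen level. Breaths are half-sine EAdi
bursts (period uniform on 2–4 s, inspiratory fraction 0.4) on a 0.5 µV
tonic baseline, with 5% multiplicative breath-to-breath amplitude jitter.
Below the planted transition the burst peak is fixed at 10 µV, so peak
Paw rises linearly with the staircase; at and above it the drive is
down-regulated instantaneously so that peak Paw plateaus at the
transition-continuity value (level × 10 cmH2O); a `phase2_creep` knob can
add a residual "less steep increase" instead of a hard plateau, but the
default is the hard plateau the two-phase description idealizes.
Inspiratory flow is a half-sine lobe integrating to
Vt = 0.25 L + 0.02 L/cmH2O × peak Paw (a spontaneous volume plus a
compliance-like assist contribution); expiration is a volume-conserving
decaying negative lobe. White Gaussian noise (0.1 µV on EAdi, 0.01 L/s on
flow) and ~2/min sub-100 ms false-trigger blips complete the session.
Everything derives from one `numpy` generator seeded by `seed`.

Not modelled: cardiac contamination of EAdi, dynamic (non-instantaneous)
down-regulation, resistance/elastance lung mechanics, leaks, and coloured
noise. Passing benchmarks on these sessions therefore shows that the
pipeline recovers the planted two-phase geometry under realistic timing,
amplitude, noise and artifact conditions — not that it is robust to every
pathology of real recordings.

## Benchmark results and known limitations

Problem sizes: benchmark suites use 25 sessions (breath detection) and 50
sessions (end-to-end recovery, 10 per planted level in
{1.5, 2.0, 2.5, 3.0, 3.5} cmH2O/µV) of ~1180 s each.

* **Titration window**: recovered exactly or within one titration step on
  default sessions; breath *counts* are within ±2% of truth.
* **Boundary blur in breath detection**: the causal order-40 MA delays and
  stretches the envelope by up to 0.64 s and frames quantize boundaries to
  0.24 s, so detected inspirations systematically extend ~2–3 frames past
  the planted burst. Measured against planted bursts: frame-label F1
  ≈ 0.73 and median interval IoU ≈ 0.56 — close to the closed-form
  expectation IoU ≈ Ti/(Ti + 0.88 s) for inspirations of 0.8–1.6 s. Peak
  localization is unaffected (the peak lies inside the stretched
  interval), which is why downstream recovery does not suffer.
* **Resolution of the decision**: the degree-10 polynomial smooths the
  response knee over ≈ N_TD/K, i.e. ~5 titration steps ≈ 0.5 cmH2O/µV,
  and on an ideal ramp-plateau the bare information minimum lies well past
  the knee; the fuzzy prior pulls it back to ≈ knee + 0.4–0.5. End-to-end,
  the estimate exceeds the planted transition by ~0.5 with high
  concordance (r ≈ 0.95) and strictly increasing medians across planted
  levels; |error| ≤ 0.5 in ~70% of sessions. Transitions in the upper half
  of the staircase are hardest: the quarter-point prior actively disfavors
  them, and with a hard plateau the far end of the window competes with
  the knee region.
* The method is offline by design; real-time identification would require
  restructuring steps 1 and 3–4.
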