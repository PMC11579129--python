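# Methods

## The ndRMS statistic

For an electrode pair and a (band-filtered) trial, each channel's trial
segment is z-normalized with the **population** standard deviation
(divide by N).  ndRMS is the RMS of the difference of the two
normalized segments.  The population denominator is a deliberate
choice: it makes the identity

    ndRMS = sqrt(2 (1 - r)),   r = Pearson correlation,

exact at finite trial length, so the theoretical anchors — 0 for
identical signals, sqrt(2) at r = 0, 2 at r = −1 — hold without
asymptotic caveats, and `ndrms_oracle` can serve as an exact
independent cross-check of the direct difference-RMS computation (the
implementation computes the difference RMS directly, also in the
vectorised per-pair path, so the identity remains a genuine dual
route).  For integer-cycle equal-frequency sinusoids with phase lag
phi, ndRMS = 2|sin(phi/2)|.

Trial handling: in **awake** mode the statistic is computed per rest
trial and summarised as the median over trials (robust to outlier
trials; the midpoint is used for even counts).  In **stream** mode
(anesthesia recordings, no task structure) one value is computed over
the entire recording.  A trial with (near-)constant signal on either
channel cannot be normalized; such pair-trials are excluded
(threshold: sd below 1e−12 of the series scale), and a pair is dropped
entirely when more than half of its trials are degenerate.  The
behaviour for zero-variance trials is this package's choice; it is
reported rather than silently imputed.

## Aggregation over distance and participants

Pairs are grouped into equidistant IED bins by rounding the
centre-to-centre distance to 0.1 mm (so the 3 mm lattice diagonal,
4.2426 mm, labels as 4.2 mm); bins with fewer than 10 pairs are
discarded.  Bin means are averaged recording → participant (over task
repetitions) → group (over participants, keeping only bins present in
at least two participants).  Group means are convex combinations of
participant means by construction.

## Grid comparison

HD (3 mm square lattice) and UHD (0.9 mm) grids share only two
comparable IEDs.  A 0.9 mm **square** lattice cannot produce IEDs near
3.1 and 4.1 mm (no integer a²+b² gives ≈11.9 or ≈20.8), whereas a
0.9 mm **triangular** lattice gives 0.9·√12 ≈ 3.118 and
0.9·√21 ≈ 4.124 mm — matching the 3.0/3.1 and 4.2/4.1 mm pairings the
analysis relies on.  Both constructors are provided; the triangular
layout is the UHD default, as an inference rather than an asserted
fact.

At each matched IED, the per-band values (eight dyadic bands plus the
unfiltered signal — nine per grid) are compared with a two-sided
Wilcoxon rank-sum test, Bonferroni-corrected over the number of
matched IEDs.  The reported statistic W is the rank sum of the
lower-ranked sample, with midranks for ties; under complete separation
of two 9-value samples W = 45 with exact two-sided p = 2/C(18,9) =
2/48620 ≈ 4.1e−5.  Exact p-values are used for sample sizes up to 12
(cross-checked in the tests against full permutation enumeration),
the normal approximation beyond.  The nine-values-per-grid reading is
the only one under which W = 45 is attainable, which is why it was
adopted.  A per-IED median over bands is also emitted as a summary
view.

## Preprocessing

The stage order is fixed: bad-channel masking → notch → common median
reference → band operations → segmentation.  All filters are
Butterworth, applied zero-phase (forward–backward `sosfiltfilt`);
zero-phase application avoids direction-dependent phase distortion
that would bias a phase-sensitive statistic.  Stated orders describe
the designed filter before the backward pass; a "4th-order band-stop"
is `butter(4, btype="bandstop")`, i.e. four poles per band edge,
following the MATLAB convention of the ecosystem this pipeline mirrors.

- **Notch**: cascaded ±1 Hz stop bands at 50 Hz and 24 Hz and all
  integer harmonics up to 499 Hz (the top analysis-band edge).
- **Common median reference**: per-sample median across good channels
  subtracted from every good channel (more robust than a common
  average); idempotent, and leaves the per-sample median exactly zero.
- **Band-pass**: order 3 for 1–4 and 4–8 Hz, order 4 for the higher
  bands; the "unfiltered" sentinel passes data through.  Filtering is
  applied to the continuous recording *before* segmentation, because
  1–1.75 s trials are too short to band-pass at 1–4 Hz without severe
  edge effects.
- **Bad channels**: flagged for flat signal (sd < 1e−8 µV), abnormal
  robust amplitude (channel MAD > 5 scaled MADs from the cross-channel
  median), excessive line noise (50±1 Hz power > 0.5 × total
  1–499 Hz power) or outliers (> 1 % of samples beyond 5 sd).  These
  thresholds are this package's declared defaults — the literature
  method they descend from does not publish values — and a channel
  report is always emitted for visual confirmation.
- **Morlet band power** (correlation and task analyses only; ndRMS
  uses Butterworth filtering): 7-cycle complex Morlet wavelets at five
  log-spaced frequencies per band, squared magnitude averaged over
  frequencies.  On short epochs the cycle count is capped per
  frequency so the wavelet (≈10 σ long) fits within ~90 % of the
  epoch; below half a cycle the operation errors.  Sub-7-cycle
  wavelets at 1–4 Hz on 1.5 s trials are coarse band estimates —
  accepted, since the trials cannot be lengthened.
- **Segmentation**: `half_isi` (rest = half the inter-stimulus
  interval before onset, active = half after; the ISI is the median
  onset difference) or `fixed_1p5s` (±1.5 s) schemes; half-open sample
  intervals; out-of-bounds trials dropped.

## The forward simulator

The patient data behind the method are not shareable, so the package
ships a forward model generating epicortical potentials with the
mechanisms the analysis is sensitive to.  Sources on a planar lattice
(spacing defaults to the electrode pitch) carry:

- **Traveling oscillations**: planar waves with phase
  2π·f·(p·d̂)/v at position p; conduction speeds default to the
  2–3 m/s range of short cortico-cortical connections.
- **Broadband 1/f² activity**: each component is a stationary Gaussian
  random field produced by random plane-wave synthesis — 256 spatial
  modes with wave vectors drawn from the spectral density of the
  Gaussian covariance exp(−d²/2ℓ²), each mode carrying an independent
  1/f-shaped time series.  This construction has domain-independent
  statistics (lattice smoothing was rejected: its boundary handling
  distorts correlations whenever the grid is not much larger than ℓ).
  A config may stack several components, e.g. a mesoscale shared field
  plus fine sub-electrode structure.
- **Volume conduction**: every recording point sees the sum of all
  source series weighted by exp(−d/λ).  A single exponential decay
  constant, not a biophysical head model: monotone, positive, and
  sufficient for the qualitative regimes being tested.
- **Electrode aperture**: each contact averages the field over a fixed
  sunflower pattern of sub-points on its exposed disc, so the
  electrode-size effect is deterministic given the geometry
  (seed-independent).  The disc must not exceed the pitch.
- **Sensor noise**: independent white noise per channel.
- **Task modulation**: an extra oscillation gated on during active
  trial windows with a Gaussian spatial footprint, for the task-map
  analysis.

All randomness flows from one seed through a documented split
(child 0: broadband mode draws, child 1: sensor noise).  Units are
nominal microvolts.

Two reference configurations are frozen:

- `default_config` — resting sensorimotor cortex at grid scale: theta
  / mu / beta traveling waves (5, 10, 22 Hz; 25, 15, 8 µV; distinct
  directions), one 10 µV broadband field with ℓ = 2 mm, λ = 1 mm,
  3 µV sensor noise.  Source spacing defaults to the pitch, which
  resolves inter-electrode structure but *not* sub-electrode
  structure; this keeps a 96-channel simulation tractable.
- `fine_grained_config` — for electrode-size questions: a 0.25 mm
  source lattice, λ = 0.3 mm, a 10 µV mesoscale field (ℓ = 4 mm) plus
  a 25 µV fine field (ℓ = 0.2 mm), 0.5 µV noise, 16 disc sub-points.
  Disc averaging suppresses the fine (non-shared) component on 1 mm
  contacts but not on 0.2 mm contacts, so smaller electrodes record
  larger ndRMS at matched IED — the direction observed empirically.

What the simulator does **not** emulate: cortical folding (all
geometry is planar; sulci are known to decouple nearby electrodes),
laminar source structure, spiking, non-stationarities, amplifier
artifacts beyond white noise, and anesthesia pharmacology (the
"stream" mode differs only in trial handling).  Passing simulator
tests therefore demonstrate that the *pipeline* recovers the
engineered spatial structure, not that cortical tissue behaves like
the model.

## Task-response mapping

Trial-mean 64–128 Hz Morlet power is correlated with the binary
rest/active regressor; signed R² = sign(r)·r², with two-sided p from
t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom (p = 0 at |r| = 1
by convention).  Significance is Bonferroni-thresholded by the number
of channels entering the analysis (good channels); zero-variance
channels are reported untested and still count in the denominator
(conservative).  Power is correlated raw by default; a log transform
is available but off, as the choice is not standardized.

## Problem sizes and numerical choices

Simulation-based tests run at desk scale, chosen so the full suite
completes in a few minutes on one CPU: distance curves use a
96-channel grid at 6 s; the electrode-size comparison uses 3×6-contact
grids at 2 s with 20 fixed-seed replicates per contact size
(one-sided rank-sum across replicate bin means); the noise-floor check
uses 5 s.  Distance rounding (0.1 mm), the min-pairs rule (10), the
degenerate-trial threshold (1e−12 relative sd), and the exact-p
sample-size cutoff (12) are all configurable.  Greedy nearest matching
pairs IED bins across grids within 0.2 mm, each bin used once.

## Known limitations

- The ndRMS-vs-correlation relation holds exactly per trial and pair;
  after medians over trials and means over pairs the two aggregations
  no longer map onto each other analytically, so correlation curves
  are computed independently rather than derived.
- EDF output uses a minimal single-record 16-bit writer (read back via
  MNE); long recordings round-trip within quantization but the writer
  does not chunk records or store annotations.
- The exponential conduction kernel and plane-wave fields are
  phenomenological; absolute ndRMS levels in simulation should not be
  read as predictions for tissue, only the ordering effects
  (distance, contact size, band) are meaningful.
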