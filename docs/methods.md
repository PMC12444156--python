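# Methods

## Scope and data model

`armkin` quantifies upper-limb movement quality from marker-based 3D
kinematics. A *recording* is a strictly increasing time series (UNIX seconds)
of millimetre positions for up to eight landmarks — left/right wrist, elbow
and shoulder, trunk, and an optional neck — plus a per-row iteration label.
Movements must be pre-segmented: a segment is a maximal run of identical
non-rest labels, with onset `t0` and offset `t1` the run's first and last
timestamps (both inclusive). The library performs no automatic onset
detection, no gap interpolation for marker dropout, and no filtering by
default; those are deliberate non-goals so that every reported number is a
transparent function of the input samples.

Millimetres and seconds are load-bearing: the velocity-peak threshold
δ = 20 mm/s only makes sense on that scale. A `unit_scale` factor converts
metre-based files on read.

## Differentiation

Speed, acceleration and jerk come from repeated numerical differentiation of
position. Interior samples use three-point Lagrange central differences with
non-uniform support (second order, exact on quadratics). The two samples at
each boundary use one-sided four-point stencils whose weights are solved from
the Vandermonde moment conditions (third order, exact on cubics). The
higher-order boundary treatment is not cosmetic: jerk is the third
derivative, boundary error compounds at each pass, and with second-order
edges the integrated squared jerk of an ideal reach at 200 Hz misses its
analytic value by an order of magnitude more than with third-order edges.

No smoothing is applied before differentiation. Noisy sources (IMUs, depth
cameras) should be low-pass filtered upstream; the metrics assume the samples
are trustworthy.

## Metric definitions and numerical choices

- **MT, MV, PV, velocity ratio, TPV** are direct functionals of the
  segment's speed profile (Euclidean norm of the wrist velocity). TPV ties at
  the maximum resolve to the earliest sample, since the metric measures how
  early peak speed occurs.
- **NPV** scans the speed profile left to right and accepts a peak when
  (1) it is a strict local maximum — plateaus are collapsed to their first
  sample, since strict inequalities leave them undefined; (2) it rises more
  than δ above the most recent local minimum (or the segment start);
  (3) at least τ has elapsed since the last *accepted* peak. A candidate
  rejected by the refractory rule does not reset the refractory clock.
  Defaults δ = 20 mm/s, τ = 150 ms; both are exposed because appropriate
  values depend on the speed scale of the task.
- **Acceleration zero-crossings** count sign changes of the tangential
  acceleration (first derivative of the speed profile; an angular variant
  accepts a joint-angle second derivative). Exact-zero samples are skipped
  and the comparison uses the nearest non-zero neighbours, so a
  touch-without-cross counts 0 and a crossing that lands exactly on zero
  counts 1 — a strict-product indicator would silently miss it. The pipeline
  counts crossings on interior samples only: a one-sided boundary estimate of
  a near-zero endpoint acceleration carries an arbitrary sign and would add
  spurious crossings.
- **LDJ** is `−ln((MT⁵/PL²) ∫‖j(t)‖² dt)` with the integral by trapezoidal
  rule over the segment; jerk is the norm of the third derivative of 3D
  position, not the derivative of tangential speed. The MT⁵/PL² normalization
  is forced by dimensional analysis (the integral has units mm²·s⁻⁵) and
  makes the measure invariant to spatial and temporal scaling, with the
  minimum-jerk optimum at −ln 720.
- **SPARC** zero-pads the speed signal to length `2^(⌈log₂N⌉+4)`, takes the
  FFT magnitude, normalizes by the DC value V(0), restricts to frequencies up
  to ω_c (default 40π rad/s = 20 Hz, the band relevant to volitional
  movement), then trims adaptively to the last frequency where the normalized
  magnitude still reaches the 0.05 amplitude threshold, and returns the
  negated arc length of the spectrum over that band with the frequency axis
  normalized to [0, 1]. This is the established public recipe for the
  measure; a dense-grid (10× padded) independent implementation agrees within
  0.01 on the minimum-jerk profile and serves as the cross-check in tests.
  Non-uniformly sampled profiles (interval spread above 1% of the mean) are
  linearly resampled first; I/O itself never resamples.
- **HPR and target error** are computed only when a target is configured
  (per-side config or `target_x/y/z` columns), mirroring datasets that lack
  target/end-effector annotations; the report records an explicit skip reason
  otherwise.

## Joint angles and ROM

The elbow angle is the clamped arc-cosine between the upper-arm vector
(shoulder → elbow) and the forearm vector (elbow → wrist); 0° is a fully
extended arm (the literal vector convention; clinical flexion is the same
number). For the shoulder, a virtual trunk point is placed horizontally from
the shoulder along the neck → shoulder direction (component along the up axis
removed; default up axis +z, configurable, as lab conventions differ), and
the angle between upper-arm and shoulder → trunk-point vectors is reported.
The construction emulates goniometer alignment against the trunk; the offset
magnitude (default 100 mm) provably cancels in the angle and exists only for
visualization. A sign flag flips to the shoulder → neck reading for setups
wired the other way. When the neck marker is absent it is estimated as the
shoulder midpoint — the simplest estimator that fixes the horizontal
neck-to-shoulder direction correctly for a level shoulder girdle — and the
choice is recorded in the recording's metadata.

ROM is max-minus-min of the angle series, per segment or over the whole task.
Degenerate frames (zero-length limb vectors, neck directly above the
shoulder) raise an error naming the frame; silently interpolating clinical
angle data would be worse than failing.

## Synthetic generator

The generator is the oracle source, not a simulation of a capture system. A
reach moves the wrist along `x(τ) = D(10τ³ − 15τ⁴ + 6τ⁵)` — the minimum-jerk
trajectory, whose closed forms (MV = D/T, PV = 1.875·D/T, ratio 8/15,
TPV 50%, LDJ = −ln 720, one peak, one acceleration zero crossing, HPR 1)
anchor every metric test. The elbow follows by two-link inverse kinematics
(upper arm 300 mm, forearm 280 mm, adult averages; metric values are either
invariant to them or scripted through them), trunk and neck stay static, and
a rest-labelled minimum-jerk return separates iterations. Time grids use
`N = round(T·rate)` samples at `t = k/rate`, so a 1 s segment at 200 Hz has
200 samples and MT = 0.995 s. Composed submovements are summed displacement
profiles with configurable onsets; angle sweeps run one joint through a
sinusoid by forward kinematics. Marker noise is isotropic per-frame Gaussian,
reproducible from a seed — the simplest stand-in for marker jitter.

What the generator does *not* emulate: marker occlusion and dropout,
soft-tissue artefact, correlated sensor noise, trunk compensation, or
postural drift. Passing tests therefore demonstrate numerical correctness of
the metric definitions on clean kinematics, not robustness to real capture
pathology — on real data the preprocessing caveats above apply.

## Problem sizes and determinism

The canonical validation conditions are D = 300 mm, T = 1 s at 200 Hz,
noise-free; degradation trials compose k = 1, 2, 3 submovements with onset
gaps drawn from 0.55–0.85 s, amplitudes 80–120 mm (three submovements must
stay inside the 580 mm arm reach) and 0.05 mm marker noise over 20 seeded
trials. The whole suite and the acceptance script run in seconds. All
randomness flows through explicit integer seeds; identical input and
configuration produce identical reports.

## Known limitations

- Segmentation must be provided; there is no velocity-threshold onset
  detection.
- No smoothing/Kalman/spline differentiation variants; heavy marker noise
  biases speed (rectified noise) and especially jerk-based metrics.
- Shoulder angle assumes a meaningful horizontal neck → shoulder direction;
  extreme trunk lean degrades the goniometer analogy (no trunk-compensation
  correction is applied).
- NPV with its default δ is tuned to reaching-scale speeds; slow angular
  profiles need adjusted thresholds.
- SPARC is validated on translational speed profiles; applying it to angular
  speed is possible but not covered by the oracle suite.
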