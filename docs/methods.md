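# Methods

## The model and the statistic

In the sagittal plane, single inverted-pendulum (IP) stance obeys

```
x − p_x = e_x = I_a/(m g h) · ẍ = I_a/(m² g h) · GRF_x
```

with `x` the AP COM projection (mm), `p_x` the AP COP (mm), `GRF_x` the AP
shear force (N), and anthropometrics in SI (`m` body mass excluding feet,
`h` COM height above the ankle, `I_a` sagittal moment of inertia about the
ankle, `g` gravity). Two facts are used separately:

1. `GRF_x = m ẍ` is Newton's law — always true, model-free;
2. `e_x ∝ GRF_x` is the IP prediction — true only insofar as the body
   sways as one segment.

The **IPVI** is the Pearson correlation between `e_x` and `GRF_x` over the
valid samples of a trial or window. Because (1) is used to *reconstruct*
`x` and (2) is only *scored*, the index is a genuine measurement of IP
validity rather than a tautology.

## COM reconstruction (zero-point-to-zero-point double integration)

Whenever `GRF_x = 0`, (2) forces `x = p_x`. Between consecutive zero
crossings `t_i < t_{i+1}` of the (low-pass-filtered) `GRF_x`:

```
x(t) = (1/m) ∬_{t_i}^{t} GRF_x dτ² + C1 (t − t_i) + C0
```

with `C0, C1` fixed by `x(t_i) = p_x(t_i)` and `x(t_{i+1}) = p_x(t_{i+1})`.
Note the integrand coefficient is `1/m` (Newton), not the IP slope
`I_a/(m² g h)`: the IP constant predicts the *slope* of `e_x` vs `GRF_x`
but plays no role in reconstructing `x`. Consequently only `m` of the
anthropometric block affects the estimate; `h`, `I_a`, `g` matter for
simulation and for interpreting the slope.

Numerics and edge rules:

* Crossings are located by linear interpolation between bracketing
  samples; an exact-zero sample is a crossing at that sample (runs of
  zeros collapse to the first). Crossings closer than `min_gap_s`
  (default 0.02 s ≈ 10 samples at 512 Hz) to the previous retained one
  are merged — sub-gap segments are below the 5 Hz filter's resolvable
  timescale and carry no COM information.
* The double integral uses the cumulative trapezoidal rule twice on a
  local axis consisting of the two off-grid crossing instants plus the
  enclosed grid samples, so partial first/last steps are handled at
  trapezoid order with no tuning.
* Segments with fewer than 3 grid samples are numerically
  underdetermined and flagged invalid; samples before the first crossing
  and after the last are invalid (the two boundary conditions do not
  exist there) and are excluded from all features rather than
  extrapolated.
* `e_x = x − p_x` is NaN outside the valid mask and exact inside it.

On an analytic construction (0.4 Hz, 10 mm sinusoidal COM with exactly
consistent COP/GRF) the reconstruction error is limited by trapezoid
truncation only, ~3·10⁻⁵ mm RMS at 512 Hz.

## Signal conditioning

* **Filtering**: 6th-order Butterworth low-pass at 5 Hz applied forward
  and backward (`sosfiltfilt`, reflective padding of 3×order samples).
  Zero phase is essential: a causal filter would delay COP relative to
  GRF and bias the correlation. The two-pass magnitude is squared, so
  the contract gain at the cutoff is |H|² = 0.5.
* **Resampling** (used for scatter exports, not for features): linear
  interpolation, legitimate because signals are already band-limited to
  5 Hz; a 30 s span at 30 Hz including both endpoints has 901 points.
  Features default to the filtered native rate (512 Hz).
* **Windows**: 1-s non-overlapping windows laid out on the trial clock
  (30 per 30 s trial, deterministically), with validity filtering only
  *inside* each window. Window IPVI is NaN when fewer than 2 valid
  samples remain or a channel variance vanishes; window MV_AP uses the
  full window because COP is always measured and a path length over a
  gapped mask would be biased.
* **Median split**: windows with defined IPVI are stably sorted by IPVI
  descending; the first ⌈n/2⌉ form the "larger" half. Tie and odd-count
  rules are fixed this way for determinism.

## Simulator

The generator exists so that every estimator can be validated against a
known COM; its parameters are modelling choices, not estimates of any
dataset.

**Single IP**: `I_a θ̈ = m g h sin θ − τ`, ankle torque
`τ = k_p θ + k_d θ̇ + η(t)`. COP from the small-angle plate equation
`p_x = τ/(m g)` (massless feet, plate origin at the ankle), COM
`x = h sin θ`, `GRF_x = m · d²(h sin θ)/dt²`. By construction the
COP-error/GRF identity holds exactly in the small-angle limit, so
pipeline IPVI ≈ 1 is the ground-truth expectation.

**Two-link (ankle–hip)**: absolute segment angles follow the standard
manipulator-form equations with gravity, PD joint torques and independent
noise per joint; COP again from the ankle torque, `GRF_x` from the
mass-weighted COM acceleration. With `hip_locked` the reduced composite
single-pendulum dynamics are integrated and reproduce `simulate_ip` with
the composite `m, h, I_a` bit-for-bit (the hip torque is internal to a
rigid body and cancels). Hip stiffness `k_hip` is the multi-segment dial:
at 10⁴× the ankle stiffness the trajectories match the composite IP to
≪1% of sway range; at 1× the IPVI drops by ~0.1.

Numerical choices:

* Fixed-step classical RK4 at the 512 Hz output rate; deterministic
  sub-stepping keeps `dt · ω_max < 0.5` when joint stiffness pushes the
  fastest linearized mode near the RK4 stability edge. Noise is always
  generated on a fixed half-step grid (2×fs) and interpolated to
  sub-step nodes, so paired-seed runs of different models share one
  noise realization.
* Motor noise: Gaussian white torque noise shaped by a 2nd-order
  Butterworth low-pass (default 2 Hz) and rescaled to the exact target
  SD; this produces realistic 0.1–1 Hz sway spectra.
* Fall detection: |angle| > 0.5 rad raises `FallError`. Statically
  unstable configurations (`k_p ≤ m g h`, or an unstable linearized
  two-link system) warn at construction and typically fall at run time;
  they are constructible on purpose so the failure mode is testable.
* Defaults: `m = 70 kg`, `h = 0.9 m`, `I_a = m h²` (point-mass pendulum —
  the conventional first approximation; only `m` enters reconstruction,
  so this choice does not move the IPVI). Ankle `k_p = 800 N·m/rad`
  (~1.3× the toppling stiffness `m g h ≈ 618`), `k_d = 350 N·m·s/rad`.
  Segments: legs 24.5 kg / 0.8 m, HAT 45.5 kg with COM 0.32 m above the
  hip — composite COM height 0.885 m. Noise SDs (ankle 0.4, hip
  0.25 N·m) were chosen so simulated MV_AP falls in the physiological
  4–8 mm/s range.

**Synthetic cohort**: two groups × 20 subjects × 12 trials (3 per session
× 4 sessions) × 30 s, all from one master seed via a spawned
`SeedSequence` tree (byte-reproducible). The "older" group draws a stiffer
hip (normal 2500 ± 400 N·m/rad) and stronger ankle noise (0.55 ± 0.08 N·m)
than the "younger" group (350 ± 60, truncated at 265 N·m/rad just above
the linear stability boundary ≈ 255; noise 0.35 ± 0.06). This
parameterization *mimics the expected ordering* — older: higher IPVI and
higher MV_AP — as a modelling choice; it does not claim to reproduce any
empirical group values.

## Cohort statistics

* Group comparison: per-subject means over all trials, compared by a
  two-sided equal-variance Student's t-test (df = n_a + n_b − 2). Equal
  variance is deliberate — it is the plain "independent Student's
  t-test" — and no multiple-testing correction is applied.
* Median-split comparison: per subject, the mean window MV_AP of the
  larger and smaller IPVI halves; group-wise independent t-test between
  the two sets of per-subject means.
* Classification: each subject contributes the means of every unordered
  k-subset of its trials (k = 3 of 12 → C(12,3) = 220 samples/subject,
  4,400 per 20-subject group), enumerated lexicographically. Scores are
  ranked by ROC AUC (trapezoidal = tie-corrected Mann–Whitney; positive
  class = older, higher score ⇒ positive) and by the best single
  threshold's resubstitution accuracy (midpoints between distinct sorted
  scores, both orientations, ties toward the lower threshold).
  Caveats, by design: subset means from one subject are heavily
  dependent, and resubstitution accuracy is optimistic — these mirror
  the simplest protocol consistent with single-feature ROC analysis and
  are reported as such, not as generalization estimates.

## What passing the simulator-based checks does and does not show

The simulator validates the *estimation machinery*: crossing detection,
boundary-value integration, windowing, statistics. Real force-plate data
additionally contain sensor noise and drift, non-stationarity, breathing
and cardiac artefacts, finite-foot effects on the plate equation, and
anthropometric uncertainty — none of which the generator emulates beyond
band-limited motor noise. High IPVI on simulated IP sway is a correctness
check, not evidence about human sway; group differences on the synthetic
cohort demonstrate sensitivity of the pipeline, not physiology.

## Problem sizes used in automated checks

The test suite simulates single trials of 10–30 s and a reduced cohort
(8 subjects × 6 trials × 20 s per group) for the directional group check;
the acceptance script runs the full default cohort (20 × 12 × 30 s per
group) and a 4-decade hip-stiffness sweep with 10 paired-seed trials per
level. These sizes were chosen to keep routine runs fast while leaving the
statistical conclusions unchanged.
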