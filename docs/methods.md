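# Methods

This note documents the models implemented in `phosphenes`, the choices
made where the underlying methods are under-specified, what the synthetic
data generator does and does not emulate, and the numerical details that
matter for reproducing results.

## Coordinate systems and units

All modeling happens in a fovea-centered retinal frame in microns, with
`x` positive toward the optic disc (nasal retina) and `y` positive toward
superior retina. Both eyes are represented in this nasal-positive frame,
so a left eye differs from a right eye only when realized anatomically
(one x-mirror, applied exactly once when building arrays and maps).

Retinal distance and visual angle are related by a linear conversion of
3.6 deg/mm by default, applied radially from the fovea. This matches the
common anchor values for the human eye (1 mm ↔ 3.6°, 437 µm ≈ 1.6°,
1,420 µm ≈ 5.1°). The conversion is a pluggable pair of callables, so a
nonlinear eccentricity-dependent formula can be substituted without
touching any other module; the linear form is the default because every
quantity the package is validated against is stated at that scale.

The optic-disc landmark is specified in degrees *on retinal axes*
(nasal-positive, superior-positive), the convention in which fundus-derived
implant landmarks are reported (e.g. "15.5° nasal, 1.5° superior"). The
vertical flip to visual-field orientation (superior retina ↔ lower visual
field) is applied only when exporting images.

## Axon bundle trajectories

Nerve fiber bundles are modeled as spirals in a polar frame `(r, phi)`
centered on the optic disc (degrees),

    phi(r) = phi0 + b(phi0) * (r - r0)^c(phi0),

with separate superior (`phi0 > 0`) and inferior (`phi0 < 0`)
parameterizations of the curvature `b` and exponent `c` (hyperbolic-tangent
forms anchored at `phi0 = 121°` superior and `phi0 = -90°` inferior). The
branch is chosen on the sign of `phi0`: that is the only reading under
which both branches are reachable, since `r` is a radius and nonnegative.

Numerical choices:

* starting-circle radius `r0 = 4°` (taken from the source trajectory
  model; this paper-level constant is configurable);
* default sampling: 500 bundles, `r` from 4° to 45° in 0.25° steps;
* `phi0` is sampled at half-step offsets over (−180°, 180°), which avoids
  both the raphe (`phi0 = 0`) and the degenerate seam at `|phi0| = 180°`
  where a trajectory would exit its hemifield immediately;
* trajectories are truncated where `|phi|` would exceed 180°, so no bundle
  crosses the horizontal raphe temporal to the disc;
* the disc's elevation offset is applied only nasal of the disc when
  translating to the fovea-centered frame. This keeps the
  superior/inferior seam on the horizontal through the fovea temporally
  (matching fundus-map reconstructions) while placing the disc at its
  estimated elevation. The price is a small vertical discontinuity on the
  vertical through the disc, far from any implant location.

A property of this trajectory family worth knowing: near the *temporal*
raphe the bundles meet the seam at a steep angle (a herringbone pattern,
~60° at 15–20° eccentricity), while bundles flanking the raphe *between
fovea and disc* run essentially horizontally. Tests assert both behaviors;
an intuition that "raphe fibers are horizontal everywhere" does not hold
for these published coefficients.

Nearest-bundle queries use a k-d tree over all bundle vertices; the
tangent at a query point is the axial angle (mod 180°) of the polyline
segment at the closest vertex.

## Percept models

**Scoreboard.** An electrode at retinal position `(x_s, y_s)` produces the
isotropic Gaussian intensity `exp(-d²/(2 rho²))`, thresholded at
`1/sqrt(e)` so the binary percept is a disc of radius `rho`.

**Axon map.** Each pixel is treated as a ganglion-cell soma assigned to
its nearest bundle; its axon is the disc-ward part of that bundle. The
pixel's intensity is the maximum over axon path points of

    exp(-d_elec² / (2 rho²)) * exp(-d_soma² / (2 lambda²)),

where `d_elec` is the distance from the path point to the electrode and
`d_soma` the *arclength* from the soma to the path point. The image is
normalized to peak 1 and thresholded like the scoreboard.

Choices and their rationale:

* `d_soma` is measured along the fiber because axonal activation
  propagates along the axon; a Euclidean mode is available as a flag and
  coincides with arclength for straight fibers.
* Aggregation over the path is a maximum (a fiber is recruited once any
  part of it is driven above threshold); a sum mode is available.
* For a straight fiber the model has a closed form: a soma a distance `d`
  peripheral of the electrode at orthogonal offset `t` sees intensity
  `exp(-t²/(2 rho²)) · exp(-d²/(2 (rho² + lambda²)))` — the optimal drive
  point lies *between* soma and electrode, so the effective along-fiber
  decay constant is `sqrt(rho² + lambda²)`, not `lambda` alone. The test
  suite pins this form against brute force.
* Because `(rho, lambda)` enter the intensity only through
  `u = 1/(2 rho²)`, `v = 1/(2 lambda²)` — linearly in the exponent — the
  per-pixel candidate set can be reduced, once per electrode, to the lower
  convex hull of `(d_elec², d_soma²)` pairs. Rendering at new parameters
  is then a minimum of a handful of linear functions per pixel, and
  thresholding can be done in exponent space without evaluating a single
  exponential. This is what makes swarm-based fitting with
  cross-validation affordable; the fast path is verified against the
  direct per-bundle implementation to machine precision.

The electrode-lift simulation holds `lambda` fixed (axonal sensitivity is
a tissue property) and increases `rho` (current spread grows with
electrode–retina distance); elongation of the simulated percept decreases
monotonically as `rho` overtakes `lambda`. The *absolute* elongation
values of this simulation are sensitive to the exact electrode position
relative to the raphe and to the aggregation rule; the monotone trend is
robust and is what the tests assert.

## Shape descriptors

Area, orientation and elongation are computed from raw and central image
moments. Orientation uses the two-argument arctangent,
`theta = 1/2 atan2(2 mu'11, mu'20 - mu'02)`, so vertical elongation yields
|theta| = 90°; the special case `mu'20 == mu'02` *and* `mu'11 == 0` (e.g.
a disc) is assigned `theta = 0`. Elongation is `sqrt(1 - l2/l1)` with
`l1 >= l2` the covariance eigenvalues: 0 for a circle, → 1 for a thin
line. An empty image carries NaN orientation/elongation and area 0; a
single pixel is treated as circular. Orientations are axial throughout:
differences are wrapped to [−90°, 90°), averages use the doubled-angle
circular mean.

Trial averaging aligns drawings at their centers of mass using integer
pixel shifts with a shift-equivariant rounding (`floor(x + 1/2)`), so
copies whose centroids differ by whole pixels align exactly.

## Resampling statistics

* *SEM consistency*: the observed statistic is the mean over electrodes of
  the per-electrode trial SEM of a descriptor (area SEM normalized by the
  electrode's mean area; orientation SEM on axial residuals about the
  circular mean). The null resamples electrode-sized groups with
  replacement from the subject's pooled drawings, 1000 iterations by
  default.
* *Orientation alignment*: observed is the mean over electrodes of the
  mean absolute angular error between trial orientations and the nearest
  bundle tangent at the electrode. NM1 replaces orientations with uniform
  draws on [−90°, 90°) (its null mean is 45° analytically). NM2 keeps the
  drawn orientations and re-places the array uniformly (center
  x ∈ [−6000, 4000] µm, y ∈ [−4000, 4000] µm, rotation ∈ [−90°, 90°]),
  recomputing tangents per placement.
* p-values are one-tailed with the `(1 + #{null ≤ obs}) / (1 + iters)`
  convention, which never returns exactly zero and is exactly
  discrete-uniform under the null (verified by a KS calibration test).
* Orientation variance explained is `1 - SS_res/SS_tot` with axially
  wrapped residuals, per-trial by default (a per-electrode-mean mode is
  provided); it can be negative and is reported as-is.

## Model fitting

Models are fit through descriptors only (area, orientation, elongation;
position is deliberately not compared). The cost is
`c = sum_d (1 - R²_d)` with `R²_d = 1 - SS_res/SS_tot` per descriptor
across all drawings, the predicted descriptor of a drawing being that of
its electrode's rendered percept.

Particle swarm optimization: swarm size 10 × number of parameters,
inertia 0.7, cognitive/social weights 1.5/1.5, positions clipped to
bounds (rho ∈ [10, 3000] µm, lambda ∈ [10, 5000] µm), 5 independent
restarts with the best run kept, fully deterministic given a seed.
The iteration cap is 40 with an early stop after 8 stalled iterations
(improvement < 1e-8): on this 1–2 parameter smooth cost the swarm
converges well before that, and the configuration is logged in every
`FitResult` so a deeper search can be reproduced if desired.

Leave-one-electrode-out cross-validation fits a single `(rho, lambda)`
per training fold and scores the held-out electrode's drawings with the
same cost, normalizing by the *training* set's per-drawing descriptor
variances (a 5-drawing held-out fold has near-degenerate variance of its
own). Model comparison uses a two-tailed Wilcoxon signed-rank test on
per-electrode log mean prediction errors (`log(cost + 1e-9)`); ties with
all-zero differences are reported as p = 1.

## Synthetic data generator

The generator defines the study conditions for all pipeline-level tests:

* geometry sampled from the published landmark ranges — array center
  x ∈ [−2150, −650] µm, y ∈ [−850, 400] µm, rotation ∈ [−54°, −22°]
  (spanning the four implanted subjects' estimates), disc position drawn
  from the population distribution 15.5° ± 1.1° nasal, 1.5° ± 0.9°
  superior, truncated at 2 SD;
* per electrode, the noiseless axon-map percept at the true
  `(rho*, lambda*)`; defaults `rho* = 300 µm`, `lambda* = 1000 µm`
  (mid-range of plausible fits), 12 electrodes, 5 trials;
* trial noise: centroid jitter (σ = 200 µm), rotation jitter (σ = 10°),
  log-normal area scaling (σ = 0.15), and boundary roughening.

Roughening is a *spatially correlated, mean-zero displacement of the
outline*: a smooth random field (≈1° correlation length) with 56 µm RMS
amplitude is added to the signed boundary distance and re-thresholded.
Two alternatives were rejected for cause: an amplitude defined in pixels
makes the noise depend on the analysis raster, and independent per-pixel
boundary flips produce speckle that systematically deflates elongation
and biases fitted `lambda` low by 15–20% — a generator artifact, not a
property of the fitting procedure (confirmed by ablation).

What the generator does **not** emulate: subject-specific drawing biases
(e.g. motor error structure from the tactile control task), multi-percept
trials, trial-to-trial fading, or any dependence of percept shape on
stimulus amplitude/frequency. Passing the pipeline tests therefore shows
that the estimator recovers the generating model under realistic
geometric and drawing noise — not that the axon-map model is the true
generative process of patient drawings.

## Problem sizes for routine runs

Pipeline-level tests and examples use a reduced configuration chosen as a
sensible desk-scale default: a 0.5°/pixel raster over a 30° × 28° window
covering the implant, 200 bundles with 0.5° vertex steps, and 8–12
electrodes per synthetic subject. Parameter recovery at these settings is
limited by descriptor discretization to a few percent relative error,
comfortably inside the 10% claim; full-resolution defaults (0.2°/pixel,
500 bundles) are used wherever single renders are examined.

## Known limitations

* The linear deg↔µm conversion ignores the nonlinear retinal-arc /
  visual-angle relation beyond ~15° eccentricity and ganglion-soma
  displacement near the fovea.
* The trajectory model's temporal-raphe herringbone means tangent-based
  orientation predictions are least constrained for electrodes far
  temporal near the horizontal meridian.
* Percepts are single-electrode and static; no interaction or temporal
  dynamics.
* Elongation magnitudes from the electrode-lift simulation depend on the
  under-determined electrode placement and aggregation rule; only the
  monotone trend should be compared across implementations.
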