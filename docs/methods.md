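# Methods

This note records the models, conventions, and numerical choices behind
`taskvar`, and what the synthetic-data tests do and do not establish.

## Execution frames and transforms

Execution variables live in named coordinate frames; every analysis records
the frame it was run in because the package's central subject is how results
change across frames.  Two named transform families are built in:

- absolute ↔ relative joint angles, `(φ1, φ2) = (θ1, θ1 + θ2)` — linear,
  with exact matrix Jacobian;
- polar ↔ Cartesian release variables for the skittles lever,
  `v = θ̇ L (−sin θ, cos θ)` — nonlinear, with analytic Jacobian.  The
  inverse uses the tangency of the release velocity to the lever arc.  The
  rotation sense of the lever is a convention (counterclockwise by default):
  with it fixed, the map is a bijection away from `v = 0`, where the lever
  angle is indeterminate and a degenerate-input error is raised.  The sign
  of the relative elbow angle is likewise a convention (`elbow_branch`,
  default "down").

Angles are radians internally; degrees appear only at CLI boundaries.
Transforms without an analytic Jacobian fall back to central differences
with per-axis step `1e-6 (1 + |x|)`.

## Reaching task

Two segments of 0.4 m each, shoulder at the origin.  The default geometry
places the mean posture at absolute angles (135°, 45°) and the target line
at 45° through the mean hand point.  This choice makes the segment
orientations differ by 90°, so the hand Jacobian is a scaled rotation:
isotropic hand-space noise then stays isotropic in absolute angles and the
UCM ratio benchmarks at ~100% in that frame while being several times larger
in relative angles.  The task error is the unsigned distance of the hand
from the line; a signed version (plain signed line distance) is used
internally for root finding and curvature because the unsigned valley has a
kink at its bottom.  The relative-frame ratio depends strongly on the line
orientation and mean posture, so only the *contrast* between frames is a
stable claim; the package's tests assert the contrast, not a specific
relative-frame number.

## Skittles task

Ball flight after release is the closed-form solution of an isotropic linear
restoring force toward the post (per component relative to the post,
`x(t) = [x0 cos ωt + (vx0/ω) sin ωt] e^{−t/τ}`), undamped by default.
Defaults: ω = 3.16 rad/s, post of radius 0.25 m at the origin, target at
(0, 1) m, lever pivot (0, −1.5) m with length 0.4 m, horizon one period.
These values produce a curved one-dimensional solution manifold inside the
default execution ranges (θ ∈ [50°, 75°], θ̇ ∈ [1, 15] rad/s); all are
configurable and no quantitative claim depends on them specifically.

The result of a throw is the closest approach of the ball to the target over
`t ∈ (0, horizon]`, truncated at the first post contact (such trials carry a
collision flag; no penalty constant is added, keeping the result function
well defined without inventing units).  Numerically the distance is scanned
on a dense time grid (1000 points per period); every competitive local
minimum is refined — bounded scalar minimization followed by Newton steps on
the analytic time derivative of the squared distance — because a
near-circular orbit can approach the target nearly equally twice per period
and refining only the grid argmin leaves an error floor around 1e-8 m.
With the Newton polish the result is accurate to machine precision, which
the curvature analysis requires.

A vectorized batch evaluator (used by the cost analyses) applies the same
grid with one parabolic refinement and falls back to the exact scalar path
for colliding trials; its accuracy (~1e-8 m) is ample for costs, and every
cost computation uses the batch path consistently on both sides of its
subtraction.

The manifold is extracted by per-column sign-change bracketing of a signed
miss distance (the error signed by the cross product of the ball velocity at
closest approach with the vector to the target) followed by bisection.  The
sign convention can flip at a closest-approach branch switch slightly off
the true zero set, so each bisection root is polished by a local 2-D
minimization of the squared error; vertices end up ~1e-14 from the manifold.

## UCM analysis

The Jacobian is evaluated at the sample mean of each analyzed set (also per
bootstrap draw).  Nullspace and complement bases come from the SVD.  Both
projected variances are normalized by N (not N−1); the ratio is unaffected
either way, and the convention is recorded here because the original
literature does not resolve it.  A zero orthogonal variance yields an
infinite ratio with a flag rather than an exception, since perfectly aligned
synthetic data are a legitimate edge case.  The bootstrap draws k samples of
size n with replacement (defaults 10 × 100) and reports mean and SE = SD/√k.
Note that a per-draw variance ratio is upward-biased by O(1/n); at the
default draw size this bias (~2 points) is well inside the bootstrap SE.

Whitening factors the covariance eigendecomposition into shift → rotation →
diagonal rescale, eigenvalues sorted descending and each eigenvector's first
nonzero component made positive for cross-platform determinism.  After
whitening the sample covariance is the identity, so the UCM ratio of the
whitened data is exactly 100% whatever the input anisotropy — the
constructive demonstration that anisotropy is a property of the coordinates,
not the behavior.

## TNC costs

All three costs are "original mean minus minimized mean" over a family of
operations that contains the identity, hence non-negative by construction.

- **Tolerance**: the translation grid defaults to the data's bounding box
  inflated ×3 about its center, 101 nodes per axis; the original mean is
  always included as a candidate.  After the grid pass the best node is
  polished by Nelder–Mead (fatol 1e-13).  The polish makes the reported
  minimum independent of grid placement, which is what turns the
  mathematical invariance of T under linear re-coordinatizations into a
  numerical identity (~1e-15 observed).  Ties between grid nodes prefer the
  smallest shift.
- **Noise**: shrink scales s from 1.00 down to 0.00 in steps of 0.01.
  Because affine maps commute with means, shrinking in any linearly
  transformed frame evaluates the identical physical points, so N is exactly
  invariant under linear frame changes for any result function.
- **Covariation**: the exact method solves the linear assignment problem on
  the N×N table `C[i,j] = f(x_i, y_j)` (SciPy's Jonker–Volgenant solver),
  capped at N = 500 by default; beyond the cap a seeded random-swap
  hill-climb is available.  For execution dimension > 2 the assignment is
  cycled column-wise to convergence and labelled approximate.
- **Revised covariation**: a rectangle bounds the central 95% (configurable)
  of each marginal; a total-least-squares line is fitted to the manifold
  vertices inside it (at least 3 required); coordinates are rotated so the
  fitted line runs at 45°, and the covariation cost is recomputed there.
  The procedure is idempotent when the manifold already runs at 45°, exposes
  covariation hidden by an axis-parallel manifold, and is insensitive to the
  initial rotation of the coordinates when the manifold is straight (the
  rotation composes away; only the quantile rectangle's vertex selection can
  differ).  The 95% coverage is a package default for outlier robustness,
  not an empirical constant.  The rotation is applied without per-axis
  rescaling; with unequal marginal spreads the fitted line is diagonal in
  angle rather than literally corner-to-corner of the rectangle.
- The three costs are computed independently from the raw cloud (no
  sequential application), matching how each is defined in isolation.
- **Bootstrap**: k draws of n trials with replacement (defaults 100 × 100),
  deterministic per seed; per-draw failures propagate with the draw index.
  Bootstrapped tolerance costs default to a coarser grid (41 nodes) without
  polish, which is the speed/precision trade-off appropriate for a
  distributional summary.

## Curvature

Curvature is computed on the squared-error form of the result function: the
raw error is |·|-like across the manifold, and squaring preserves the zero
set while restoring twice-differentiability.  Reported curvatures therefore
describe the squared surface.  Hessians are symmetric central differences
(default step 1e-3 in each axis's natural units); principal curvatures are
the Hessian eigenvalues normalized by (1 + |∇f|²)^{3/2}, which reduces to
the plane-curve formula in 1-D and to the raw eigenvalues on the manifold,
where the gradient of the squared error vanishes.  On-manifold vertices must
pass an error tolerance (1e-6) or they are skipped with a warning.  The
κ_min ≈ 0 statement is checked by step refinement: with machine-precision
result values the estimate scales as step², ~1e-10 at step 1e-4.

## Synthetic data

The generators emulate the study conditions; they are pure functions of
parameters and seed.

- **Reaching scenario**: 500 trials, isotropic bivariate Gaussian hand
  scatter (σ = 0.01 m) centered on the target line, mapped to joint angles
  by inverse kinematics on a fixed elbow branch.  σ is a package default —
  the UCM ratio and the cross-frame cost contrasts do not depend on it, and
  absolute cost magnitudes in millimetres are therefore not comparable to
  any particular experiment.  Hand samples outside the reachable annulus are
  re-drawn (count reported) so n stays fixed.
- **Alignment cases**: linear valley |a·x + b·y − c| with axis-parallel or
  diagonal orientation and a Gaussian cloud whose principal axis is aligned,
  unaligned, or perpendicular to it (anisotropy 3:1 by default) — the
  schematic configurations that expose the plain C cost's rotation
  sensitivity.
- **Practice sessions**: 16 days × 180 trials by default.  Day by day, the
  cloud SD decays geometrically (0.12 → 0.03 in scaled execution units, the
  angular-velocity axis scaled by 1/5 so one scalar dispersion is
  meaningful), the mean drifts along the solution manifold between
  arc-length fractions 0.2 → 0.5 with a small initial off-manifold offset
  decaying to zero, and the tangent/normal SD ratio grows to 2.  These
  values are illustrative: they reproduce qualitative practice trends
  (falling mean error, falling noise cost, growing manifold alignment), not
  any subject's magnitudes.  Passing tests on these data show the analysis
  machinery behaves correctly under known trends; they say nothing about
  real learners beyond that.

## Problem sizes and limitations

The test suite and the acceptance script run the full 500-trial reaching
protocol; skittles manifolds are extracted at 50–70 columns and curvature is
profiled at 50 vertices; trend checks use reduced schedules (8 days × 60
trials, 3 seeds) — sizes chosen to keep the suite quick while leaving every
statistical margin intact.  Known limitations: result spaces are scalar
(no multi-dimensional or time-series results); execution spaces beyond 2-D
get only the approximate column-cycling covariation; a 500-trial variance
ratio carries ~9 points of sampling SD, so single-run UCM ratios scatter
accordingly; and no attempt is made to model metric-free internal
coordinate systems — the package treats coordinate choice as an analysis
variable, not a neural hypothesis.
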