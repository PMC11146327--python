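# Methods

This note documents the models and numerical procedures implemented in
`unbendfish`, the choices made where the design was genuinely open, and what
the synthetic-data tests do and do not establish about real data.

## Shape data and superimposition

Specimens are 2D landmark configurations sharing one anatomical scheme
(default: 15 landmarks plus 4 vertebral semilandmarks, 1-based numbering in
all user-facing interfaces). Generalized Procrustes analysis removes
location (centroid to origin), size (centroid size scaled to 1) and
orientation (least-squares rotation to the consensus, iterated until the
consensus root-mean-square change falls below 1e−10, at most 100
iterations). Two deliberate choices:

- **Full-Procrustes coordinates, no tangent-space projection.** At the
  curvature magnitudes this package targets (IC ≤ 0.065, shape distances
  ≪ 0.3) the difference is far below every tolerance used here. A
  consequence worth knowing: the four similarity degrees of freedom are
  annihilated exactly for translation but only to second order in shape
  dispersion for scale and rotation, so the "rank ≤ 2p − 4" property of the
  shape covariance holds with a relative eigenvalue threshold, not at
  machine precision.
- **Reflections disallowed.** All specimens are assumed digitized in a
  consistent lateral view; a silent reflection during alignment would mask a
  digitizing error. Mixed-side data can be pre-reflected (`gpa
  --allow-reflect` flips configurations whose signed polygon area disagrees
  with the majority).

The fixed-point GPA iteration converges rapidly for clustered shapes (all
real landmark samples) but degrades as dispersion grows; on mutually
unrelated random shapes it can exhaust the iteration cap, which is reported
as a warning rather than an error because the partial optimum is still a
valid superimposition.

## Index of curvature

For the ordered axis chain (snout 12 → column start 15 → semilandmarks
16–19 → hypurals 4), with polyline arc length A and chord C:

    IC = 1 − C/A ∈ [0, 1)

This is the form consistent with all three conventions in circulation at
once: it is 0 for a straight body, bounded by 1, and equals the relative
shortening of standard length (IC = 0.0137 ⇔ 1.37 % reduction). The raw
ratio A/C (≥ 1) is available via `convention="ratio"` for comparison with
literature that reports it; at IC ≤ 0.065 the two differ by < 0.5 %
relative. IC is computed from interlandmark distances, so it is identical on
raw and Procrustes-aligned coordinates.

## Regression unbending

Each of the 2p Procrustes coordinates is regressed on IC (intercept +
slope, ordinary least squares); corrected shapes are consensus + residuals,
then re-superimposed. Residual orthogonality makes the corrected data
exactly uncorrelated with IC *before* the final GPA; the re-superimposition
rotates each shape by an O(shape-deviation) angle and can reintroduce an
association of that order — negligible in practice (R² stays < 0.01 in all
tested conditions) but not identically zero, which is why the tests assert
the R² property after re-GPA and exact orthogonality before it.

A structural limitation, visible in both the simulations and the evaluation
statistics: the regression removes only the component of arching that is
*linear* in IC. When specimens arch dorsally and ventrally in comparable
numbers the antisymmetric part of the deformation cancels in the regression
and survives the correction, so the variance reduction can be modest even
though the IC association is gone.

## Curve-fit (Tps-style) unbending

Per specimen:

1. Rotate/translate so the chord (first → last axis landmark) lies on the
   positive x′-axis from the origin; reject chains that double back along
   the chord by more than 1 % of its length (y′ = f(x′) would be
   ill-defined).
2. Least-squares polynomial fit y′ = f(x′), degree 2 or 3, through the
   chain points; the RMS residual of the chain about the curve is kept as a
   per-specimen diagnostic.
3. Remap *every* landmark to (s, d): s the arc length along the curve from
   its point at x′ = 0 to the landmark's foot (globally nearest curve
   point), d the signed perpendicular offset, positive on the left of the
   direction of increasing arc. Axis landmarks land on d ≈ 0; distances
   along the body axis are preserved.
4. Drop the semilandmarks that only traced the curvature (default 16–19),
   then re-run GPA.

Numerical choices: the foot point is bracketed by 2048 samples over the
curve's support extended 10 % beyond the chord and refined by bounded scalar
minimization to 1e−10 (robust for near-flat curves, and avoids root-finding
on the quintic that exact projection onto a cubic requires); arc length is
adaptive quadrature of √(1 + f′²) to 1e−10 absolute. A landmark whose
nearest curve point falls outside the extended support raises an error
naming the landmark. The output frame is deterministic (same input bits →
same output bits).

Degree defaults to 3: fossil arching is often irregularly sigmoidal rather
than uniformly concave, and a cubic accommodates opposite-sign curvature at
the two ends; the quadratic remains available and is selected automatically
per IC-group when `degree=None` and `groups=k` are given (equal-frequency IC
bins, smaller mean axis-fit RMSE wins). Grouping never pools specimens into
one fit — each specimen always gets its own curve in its own chord-aligned
frame, which is the only reading that makes the straightening exact per
fossil; the grouping exists as a workflow device.

The straightening is validated by round trip against the generator (below),
not against any external program's output bit-for-bit: the exact projection
and translation rules inside the original GUI implementation are
unpublished, so this operator is a reconstruction of the documented
behaviour.

## Evaluation statistics

- **Shape PCA**: eigendecomposition of the covariance of the flattened
  Procrustes coordinates (divisor n − 1); deterministic sign convention
  (largest-|loading| entry of each axis positive). Eigenvalues sum to the
  total Procrustes variance.
- **Shape-on-covariate regression**: Goodall-style pooled sums of squares
  over all 2p coordinates, F = (SS_model/1)/(SS_resid/(n − 2)); p-value by
  permutation of the covariate, p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1),
  default 999 permutations, seed required. Note that the pooled R² of a
  null regression has expectation 1/(n − 1) — at n = 90 about 0.011 — so
  small positive R² values are the no-association baseline, not evidence of
  residual curvature; the permutation p is the calibrated quantity.
- **Scalar and per-PC regressions**: classical OLS with parametric
  F(1, n − 2) tests, as in base-R `lm`. No multiple-testing correction
  across PCs (each judged at the bare 0.05 level); the CLI prints a
  Holm-adjusted column alongside, clearly labeled as an extra.
- **Welch's t** for IC differences between species, with
  Welch–Satterthwaite df (via scipy).
- **Disparity contrast**: total Procrustes variances of two datasets
  (which need not share a landmark scheme — original 19-landmark vs
  corrected 15-landmark data are comparable as variances), permutation test
  shuffling group labels over the pooled per-specimen squared
  distances-to-own-consensus. The shuffling scheme mirrors standard
  morphological-disparity pairwise tests.

## Synthetic bent fish

`template(species)` provides schematic 19-point body plans ("slender" and
"deep", the deep plan taller at the dorsal/ventral apices and pectoral
level) with a perfectly straight horizontal axis. The templates are coded
from anatomical description, not traced from images; no test depends on
matching real anatomy.

`bend` is the exact inverse of the straightening operator: a point at
(arc position s, offset d) maps to the bending curve's point at arc length
s plus d times the unit left normal. Bending is isometric along the axis —
rigor mortis bends the column without stretching it — and raises a fold
error when offsets exceed the local radius of curvature. Profiles: "arc"
(single-sign quadratic bow) and "sigmoid" (cubic with opposite-sign end
curvatures, peak deflection normalized to amplitude × span). Arc-length
inversion uses a dense Simpson cumulative integral with monotone-cubic
interpolation and Newton refinement (error ≪ 1e−9 of the span); the
realized IC of any bend is available by quadrature, measured on the same
interlandmark polyline the index uses, so generator targets and
measurements agree to 1e−6.

`simulate_sample` draws, per specimen: centroid size uniform on
`size_range` (default 30–120 mm, a few-cm fossil fish photographed to
scale); a target IC from a logistic link

    IC = ic_max · expit(η0 + slope · z + ε),  z = standardized size,
    ε ~ N(0, ic_link_sd)

with defaults ic_max = 0.065, η0 = −1.4, slope = −1.5, ic_link_sd = 0.8,
chosen so the realized IC distribution emulates the fossil study sample
(range ≈ [0, 0.065], mean ≈ 0.015, smaller specimens markedly more curved);
the bending amplitude is then solved by root finding so the noise-free bend
realizes that IC exactly. Direction is random dorsal/ventral (fixable via
`direction`), degree a 30/70 mix of quadratic and cubic (fixable via
`degree`), and isotropic Gaussian digitizing noise of sd
`noise_sd` × centroid size (default 0.002) is added last. Default sample:
60 + 30 specimens of the two body plans. The logistic link is a convenience
— no quantitative model of how taphonomic arching scales with size exists —
and is labeled as such.

**What passing tests show, and don't.** The generator produces exactly
polynomial axis curves, isotropic noise, and a shared rigid template per
species. Passing round-trip and variance-reduction tests therefore
establishes that the operators are correct inverses and that the protocol
behaves as designed under its own model; they do not establish that real
fossil arching is polynomial, that digitizing error is isotropic, or that
the corrections are unbiased when the axis chain is itself mislocated.
Compaction, shear, and non-axial distortion are outside the model entirely.

## Problem sizes and determinism

The test suite and the acceptance script run the simulated study at n = 90
(60 + 30), the scale at which the protocol's statistics stabilize, with
999 permutations for reported p-values and 199 for calibration sweeps
(200 null replicates at n = 30). Every stochastic routine takes an explicit
seed; identical seeds give byte-identical TPS output and identical
statistics.

## Known limitations

- 2D only; no sliding of semilandmarks (bending-energy or
  perpendicular-projection) before they are dropped.
- The regression correction removes only linear-in-IC effects (see above);
  a quadratic-IC design matrix would capture symmetric arching but is out
  of scope.
- Single-nuisance-vector projection (Burnaby's method) is deliberately not
  provided: arching in fossils spreads across many shape dimensions, which
  is the failure mode motivating this package.
- Per-PC significance reporting ignores multiplicity by design (matching
  common practice); treat isolated marginal PCs accordingly.
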