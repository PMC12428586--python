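# Methods

## Skeleton model

An airway skeleton is a tree of branches; each branch is an ordered
centreline polyline with a tube radius (mm) at every sampling point. The
trachea is generation 0 and each child is its parent's generation + 1. A
child's first point must coincide with a point of its parent within
0.5 mm. Radii come either directly from the source data or from a surface
mesh via the equivalent radius √(S/π) of the cross-section of area S cut
perpendicular to the centreline; near bifurcations the cutting plane
intersects the mesh in several loops and the loop whose centroid is
nearest the query point is used.

Junction radius steps are smoothed by the 20 % rule: when the relative
difference between the parent-end and child-start radii (with respect to
the larger one) exceeds the threshold (default 0.20), the three samples on
each side are replaced by a linear ramp, in arc length across the
junction, between the flanking untouched radii. The rule is applied
across junctions only, not between consecutive samples within a branch —
intrabranch steps are data, e.g. a stenosis.

Centrelines are smoothed with a cubic chord-length-parameterized spline
(`scipy.interpolate.splprep`); all control weights are 1. A smoothing
spline is free at its ends, so the evaluated curve receives the linear
correction `(1−u)·Δ₀ + u·Δ₁`, which pins both endpoints exactly without
disturbing interior smoothness. Radii are carried to resampled
centrelines by linear interpolation in arc length.

Distal trimming truncates every terminal branch at a fixed arc length
beyond its proximal bifurcation (branches already shorter are left
alone), so all transition models of a series end at the same outlets.
"Same length" is interpreted per terminal branch, not as equal total path
length from the inlet; the operation is idempotent.

## Convolution surface

The surface is the iso-level of a scalar field built from line-segment
primitives. The kernel is the truncated quartic `f(r) = (1 − r²/R²)²`
for r ≤ R, zero beyond: compact support means only skeleton within the
clipping sphere of radius R contributes, and the quartic form makes the
field C¹ at the support boundary, which is what keeps bifurcation blends
crease-free (a cubic kernel has a derivative jump there).

For a segment P₁P₂ of length l, with d = P₂ − P₁, v = P − P₁, a = d·v
and h = R² − |v|², the squared distance from P to the segment point L(t)
is (R² − h) − 2at + l²t², and the part of t ∈ [0,1] inside the clipping
sphere solves l²t² − 2at − h ≤ 0. The potential is the arc-length
integral of the kernel over that interval, which is a quintic polynomial
in t evaluated in closed form. Two numerical points:

- Expanding `(h + 2at − l²t²)²` gives the cross term −4al²t³, whose
  antiderivative is −a·l²·t⁴ (coefficient 1, not ½). The implementation
  was validated against an independent adaptive-quadrature oracle to
  1e−9·l over 1000 random configurations — the test that fixes the
  expansion unambiguously.
- The antiderivative is evaluated in the shifted variable u = t − a/l²
  (the perpendicular foot), where the quadratic becomes H − l²u² with
  H = R² − ρ² and ρ the point-line distance. Algebraically identical to
  the direct expansion, but free of the catastrophic cancellation the
  direct form suffers when l ≫ R.

The quadrature oracle integrates only over the clipped interval (the
integrand is smooth there) with tolerances 1e−12, so the 1e−9 comparison
is meaningful.

**Radius control.** The kernel has one support radius per primitive, so a
varying-radius tube is approximated piecewise: each polyline edge is
subdivided to at most the local radius in length, and each segment gets
R = s × (mean of its endpoint radii) with support scale s (default 2.0;
larger s gives smoother, slightly bulgier bifurcation blends). Each
primitive's contribution is normalized by 1/R. For an infinite straight
skeleton the field at distance ρ is (16/15)(R² − ρ²)^{5/2}/R⁴, so with
the normalization the field at ρ = r (the tube radius, R = s·r) is

    T(s) = (16/15)·(s² − 1)^{5/2}/s⁵,    T(2) ≈ 0.519615,

independent of r. One global iso value therefore renders every local
radius correctly; without the normalization no single iso level can
reproduce a varying-radius tube. Bifurcation bulging from field
superposition is accepted as the smooth transitional morphology; no
bulge-suppression weighting is applied.

**Sampling and polygonization.** The field is sampled on an isotropic
grid covering the primitives' bounding box inflated by the largest
support radius; each primitive only visits nodes inside its own support
box, so cost is linear in skeleton length and the result is exactly the
brute-force sum. Default spacing is min(radius)/6 clamped to
[0.1, 1.0] mm; a node budget (2×10⁷) guards against accidental
over-resolution. Iso-surfacing is marching cubes with linear edge
interpolation (`skimage.measure.marching_cubes`); meshes are watertight
whenever the surface stays inside the grid. Export is binary/ASCII STL
or OBJ via trimesh. Measured radius fidelity for straight tubes of radius
1–10 mm at spacing r/8 is within 0.2 %, comfortably inside the 2 % the
package tests for.

## Stenosis dilation

A stenosis annotation stores, over an arc-length interval of one branch,
the current radii R₂ and healthy radii R₁ ≥ R₂. Dilation at ratio
α ∈ [0,1] sets R = R₂ + α(R₁ − R₂) pointwise; radii outside the interval
are never modified. For rectangle-like manual annotations, the radius
change is damped linearly to zero over `ramp_margin` mm (default 2)
inside each interval edge, avoiding a step at the boundary. Profiles that
already taper to R₁ = R₂ at the edges — e.g. the cosine-shouldered
synthetic stenoses — use ramp_margin 0, which keeps α = 1 the exact
inverse of stenosis insertion (to 1e−12). The radius response is affine
and non-decreasing in α, so minimum lumen radius grows monotonically
along a transition series (default α = 0, 0.2, …, 1.0).

When no healthy reference is available, R₁ is inferred by linear
interpolation between the mean radii of 3-sample flanking windows on
each side of the interval; an interval touching a branch end has no flank
and requires a manual R₁. This flank interpolation replaces comparison
against a healthy-atlas airway, for which no data exist here.

## Flow allocation and boundary conditions

The 18 bronchopulmonary segments carry fixed ventilation fractions
(left upper lobe 6.0/6.0/4.3/4.3 %, left lower 4×6.1 %, right upper
3×6.9 %, right middle 2×4.5 %, right lower 5×4.9 %). The raw values sum
to 99.2 %; the default renormalizes them so allocated flows conserve the
total — required for a closed tree — with a flag to keep the raw values.
Trees truncated at generation 5–8 rarely have exactly 18 orifices, so a
user-supplied outlet map links orifices to segments; a segment with
several outlets splits its share equally (or by orifice area). Inlet
velocity is flow/area (1 m/s × 1 mm² = 1e−3 L/s). FEV1, a volume in one
second, is used as a flow in L/s throughout, following clinical
convention for this workflow.

Active expiration is realized as two external CFD runs connected by data
transfer only: the normal-geometry model is driven by the velocity
inlets above against a 0 Pa tracheal outlet; the orifice pressures it
produces are exported and re-used as pressure inlets for the stenotic
model (the equal-pressure assumption — valid only for patients whose
small airways are functionally normal). This package writes and reads
those CSV tables; it never solves flow.

## FEV1 regression

Each patient contributes (a, b, c): simulated stenotic-model outlet flow,
measured FEV1, predicted normal FEV1. Ratios x = a/c and y = b/c are
always computed from the unrounded inputs (fitting on 3-dp rounded ratios
shifts the slope in the fourth decimal). OLS (statsmodels) gives slope
0.8199 and intercept −0.089 on the built-in four-patient training table,
with standard errors and residual variance retained for intervals.

Metric conventions: RMSE is √(SSres/n) (population form) on training and
test alike; test R² is 1 − SSres/SStot computed on the test set itself.
LOOCV refits on n−1 records and reports each fold's held-out absolute
error together with the refit's training R² — a single held-out point has
no R² of its own. Mean-response intervals use the standard OLS formula
ŷ ± t₍n−2₎·s·√(1/n + (x − x̄)²/Sxx); at n = 4 these intervals are wide,
and clinical-report interval columns produced by other conventions will
not generally match them.

The dilation target: predicted FEV1 as a function of α is the monotone
piecewise-linear interpolant of `predict(fit, a(α), c)` over the supplied
(α, flow) grid; α* is the smallest α reaching
`target_ratio × predicted FVC` (default ratio 0.70, against *predicted*
FVC). Non-monotonicities up to 1 % of the FEV1 span are flattened with a
warning; larger ones raise. A target above the α = 1 prediction raises
with the shortfall rather than extrapolating. Producing the per-α flows
requires one external CFD run per transition model; the package is
deliberately agnostic about where that table comes from.

## Synthetic data

The fixture generators are first-class, seeded, pure functions:

- `make_bifurcating_tree`: symmetric tree, radius homothety 2^(−1/3) per
  generation (Weibel-like), length ratio 0.8, half-angle 35°, bifurcation
  planes rotating 90° per generation; root radius 8 mm / length 60 mm
  (adult trachea scale). Optional positional jitter leaves branch
  endpoints exact so attachment invariants hold.
- `insert_stenosis`: cosine-shouldered narrowing with minimum radius
  (1 − severity) × original; the returned annotation makes α = 1 dilation
  the exact inverse.
- `make_cylinder_mesh`: regular-polygon cylinder whose cross-section area
  is known in closed form — the oracle geometry for radius measurement.
- `synth_patient_records`: x uniform in (0.3, 1.0) — the ratio range the
  clinical tables span — Gaussian noise on y (default sd 0.01, matching
  the training-residual scale), c uniform in 1.4–3.5 L/s.

What the synthetic trees do *not* emulate: airway asymmetry (Horsfield
ordering), non-circular lumina, cartilage ridge geometry, CT noise and
segmentation defects. Tests passing on them demonstrate correctness of
the algorithms, not fidelity to any patient.

## Problem sizes and numerical choices

The test suite and acceptance script use: 1000 random configurations for
the closed-form/quadrature comparison (tolerance 1e−9 relative, scaled by
segment length); a ±2000 mm segment with R = 2 mm for the infinite-line
limit (1e−6 relative); tubes of radius 1, 2, 5, 10 mm, length 10r,
spacing r/8 for radius fidelity (2 %); 200 cohorts of 50 synthetic
patients for parameter recovery. Grids are float64 throughout; no global
epsilon — every tolerance is stated at its operation.

## Known limitations

- Piecewise-constant support radius converges to the varying-radius tube
  only as segments are subdivided; very steep radius gradients (change
  comparable to the radius over one radius of length) render slightly
  smoothed.
- Marching cubes at the default spacing can close off a lumen narrower
  than ~2 grid cells; the node budget then forces an explicit decision
  rather than silently degrading.
- The regression is a two-parameter model fitted on four patients; the
  package reports standard errors and LOOCV precisely because n is small.
  Nothing here validates transfer to other stenosis subtypes.
- The equal-pressure transfer is a modelling assumption, untestable
  in-package; it is data plumbing here, with its physiological rationale
  and scope (normal small-airway function) documented above.
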