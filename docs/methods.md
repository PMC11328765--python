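# Methods

This note records the models, conventions, and numerical choices behind
`confluencemorph`, and what the phantom-based validation does and does not
establish.

## Input model and conventions

The measurement chain consumes an axis-aligned 3D integer label map with
voxel spacing in mm: labels 1–7 for LA, confluence (PVC), LUPV, RUPV, LIPV,
RIPV, and vertical vein (VV) by default, configurable via `LabelSchema`.
World coordinates are `origin + index * spacing`; oblique acquisitions must
be resampled upstream — a single axis-aligned convention keeps every
geometric quantity testable against closed forms, and all reported metrics
are frame-independent anyway. Lengths are mm, volumes cm³, body surface area
(BSA) m². BSA is always an input from the clinical record; no height/weight
formula is applied. Clinical records carry time-to-PPVS in months with an
event flag; censoring is right-censoring at last follow-up.

## Centerline extraction and confluence demarcation

Centerlines are computed by 3D medial-axis thinning
(`skimage.morphology.skeletonize`) of the venous labels, followed by
per-structure longest-path tracing on the 26-connected skeleton graph
(double-sweep Dijkstra), 3-component moving-average smoothing
(endpoint-preserving, window 5, two passes), and tangent extension of the
path ends to the label boundary. The extension step matters: thinning
retracts from a blunt tube end by roughly the tube radius, and on a 30 mm
test tube that alone is a 15% length error. Smoothing removes the
voxel-lattice zigzag that otherwise inflates arc length by several percent;
on collinear equispaced points it is exact, so a one-voxel-thick line traces
to exactly its voxel centers. Components are checked with 6-connectivity;
skeleton adjacency uses 26-connectivity.

Junctions are located from label adjacency rather than from the skeleton:
for each vein, the centroid of the shared-face surface between its label and
the confluence label (face midpoints, which lie exactly on the interface —
voxel-center centroids would be biased outward by half a voxel). The
confluence is demarcated between two planes orthogonal to the local main
channel tangent: one through the junction where RUPV and RIPV join, one
through the junction where VV and LUPV join. For right-sided vertical veins
the rule mirrors (LUPV∧LIPV and VV∧RUPV). Because both pairings involve the
same five vessels, the genuine one is recognized geometrically — the two
veins of a true end pair attach at nearly the same point. The traced channel
is clipped to the planes, linearly extending along the end tangent where the
skeleton falls short; a segment shorter than 2 voxels, or coincident
junction nodes, is a degenerate-confluence error.

## Surface, projection, and DBLC sampling

The LA surface is the marching-cubes isosurface of the LA label at level
0.5, in world mm (the mask is zero-padded by one voxel so the mesh closes at
array boundaries). The *corresponding confluence* is obtained by Euclidean
closest-point projection of each confluence centerline point onto the mesh —
chosen over normal-ray casting because it is defined everywhere, is a
contraction onto convex shapes, and matches the phantom closed forms; this
is the single most consequential modeling interpretation in the package.
Closest points are exact: a vertex KD-tree bounds the distance, candidate
triangles are culled through a centroid KD-tree, and the point–triangle
distance is computed by the standard barycentric region test. The projected
polyline receives the same endpoint-preserving smoothing as the centerlines
(isosurface faceting otherwise inflates its length by ~2–3%), and CCL is its
chordal arc length — not an exact surface geodesic; the difference vanishes
with sampling density, which is one projected point per centerline point.

The corresponding confluence is then resampled at 100 equal arc-length
stations including both endpoints (station spacing CCL/99). Each station
`p_i` pairs with the globally nearest point `q_i` of the confluence
centerline polyline (continuous over segments, not index-matched — the only
order-free reading). `DBLC_i = |p_i − q_i|` is taken unsigned; `mDBLC` is
the mean of the 100 values.

Volumes are voxel counts times voxel volume, with no partial-volume
correction. `iTVLC` is computed as `iLA + iPVC` so the additivity identity
holds to machine precision. Risk tiers use inclusive thresholds
`(iTVLC, ratio) ≥ (20.0, 7.7)` by default; these are configuration
constants, not re-derived from phantom data, and the tier function is
monotone in both markers by construction.

## Phantoms and ground truth

Two analytic families drive validation. The *slab* phantom is a box LA whose
top face is the plane z = 0 with a straight cylindrical confluence (radius
2.5 mm, length L = 30 mm) at gap d = 3 mm; truth: CCL = L, DBLC = d
uniformly, box and cylinder volumes. The *sphere-arc* phantom is a spherical
LA (R = 20 mm) with the confluence along a concentric arc of radius
R + g = 22 mm over θ = 1 rad (tube radius 1.6 mm); truth: the projection is
the concentric arc, CCL = Rθ = 20 mm, DBLC = g = 2 mm, and the tube volume
is the Pappus form πr²(R+g)θ. The wedge clip φ ∈ [0, θ] realizes exactly the
junction planes (each φ-plane contains the radial and vertical directions,
hence is orthogonal to the arc tangent). An ellipsoid variant exists for
volumetry; its gap/length truths have no closed form and are left NaN. Vein
stubs realize the supracardiac type Ia layout (RUPV/RIPV at one end, LUPV
and VV at the other, LIPV mid-channel), with a mirrored type Ib flag.
Contested voxels between stubs sharing an attachment point go to the nearest
axis, so both veins retain a contact surface. Truths are always closed
forms, never measured from the raster.

Tube radii were chosen with discretization in mind: voxel-count volume error
of a cylinder cross-section oscillates with radius/spacing, and the defaults
(2.5 mm straight, 1.6 mm arc at 0.5 mm spacing) sit at favorable points
(≤ 2% error) while respecting the gap constraints. The default test spacing
of 0.5 mm isotropic is an implementation choice; no working CTA resolution
is assumed.

At 0.5 mm spacing the full chain recovers the reference phantoms with CCL
error ≤ 1.3%, mDBLC error ≤ 0.18 mm, and volume errors ≤ 1.9%, in well under
a minute per phantom.

## Synthetic cohorts

`make_synthetic_cohort` draws per-subject slab geometries whose analytic
markers span realistic infant ranges: iTVLC ~ U(10, 30) cm³/m² (bracketing
the observed median of 20), CCL/mDBLC ~ U(3, 13) (median ≈ 8, quartiles
≈ 5–11.5), gap ~ U(1.2, 2.0) mm, BSA ~ U(0.20, 0.34) m², log-normal age
centered at 61 days, prePVO prevalence 0.34. Slab dimensions are solved so
the analytic iTVLC and ratio equal the drawn values exactly. Event times are
exponential with hazard `h0 · exp(b1·(iTVLC−20) + b2·(ratio−8))`,
h0 = 0.03/month; centering the linear predictor only rescales the baseline
and leaves Cox estimates of b1, b2 unchanged. Censoring is independent
uniform on (0, τ) with τ calibrated by bisection on the drawn sample to hit
the requested censored fraction (default 0.3); `censor_rate=0` yields a
fully observed cohort. Everything flows from one seeded generator.

Uniform marker distributions are a stand-in — no distributional description
of real confluence shapes is available — and the geometry family is a
simplification (no trabeculation, no appendage, no imaging noise, uniform
gap). Passing tests therefore demonstrate correctness of the measurement and
inference machinery under known geometry and a correctly specified hazard,
not performance on clinical CTA, where segmentation quality, anisotropy, and
anatomical variation dominate.

## Survival statistics

Kaplan–Meier estimation and the log-rank test delegate to lifelines. The Cox
model is fit in-package by Newton–Raphson on the Breslow partial likelihood
(months-scale times tie often, and Breslow keeps the brute-force oracle
simple) with internal covariate standardization, step-halving, a 1e-9
gradient tolerance, and Wald CIs/p-values from the observed information;
backward selection repeatedly drops the largest-p covariate until all
p < 0.05. On tie-free data the fit matches lifelines (Efron) to ~1e-6, and
an 8-subject grid-search oracle pins the maximizer to 1e-4.

The proportionality check uses the Grambsch–Therneau score statistic with
the rank time transform and per-event risk-set variances, including the
correction for the estimated coefficient (the computation used by modern
`cox.zph`); the average-information shortcut proved measurably conservative
(type-I ≈ 0.025 vs ≈ 0.04 at nominal 0.05 under ~50% censoring, 1000
replicates). The statistic is χ²(1); the scaled-residual/rank correlation is
reported alongside as a descriptive.

Time-dependent discrimination uses the cumulative-case/dynamic-control AUC
with inverse-probability-of-censoring weights from the censoring
Kaplan–Meier (scikit-survival's estimator); with no censoring it reduces
exactly to pair counting on the binary outcome "event by t", which the tests
assert, and it is invariant under monotone marker transforms. CIs are
seeded percentile bootstrap (default 500 resamples; resamples without events
by the horizon or subjects beyond it are redrawn). Restricted cubic spline
hazard curves use Harrell's truncated-power natural-spline basis with 4
knots at the 5/35/65/95th marker percentiles (linear-interpolation
quantiles, stated because knot placement depends on the convention), fit
through the in-package Cox routine; the curve is normalized to HR = 1 at the
cohort median with pointwise Wald bands by the delta method. Competing-risk
analysis is intentionally absent. One-year horizons are the default in the
pipeline, reflecting when PPVS hazard concentrates.

## Pipeline and problem sizes

`run_pipeline` composes phantom generation (or volume loading), per-case
quantification, and the cohort statistics into a seeded run with a
content-hash manifest; a failing case is recorded and skipped, and only zero
successes aborts the run. The CLI adds no computation.

Problem sizes used by the shipped validation: reference phantoms at 0.5 mm
(~1–3 M voxels, seconds each); Cox recovery over 100 cohorts of n = 400;
Schoenfeld calibration over 200 replicates of n = 150; null AUC over 100
replicates of n = 500; the end-to-end pipeline at 200 phantoms in the
acceptance script and 48 in the default test suite. These sizes give
Monte-Carlo error comfortably inside the asserted tolerances while keeping
the default suite fast.

## Known limitations

- Closest-point projection can fold on strongly concave atrial surfaces;
  real atria are mostly convex toward the confluence, but the behavior is
  untested beyond the phantom families.
- CCL is chordal, not geodesic; at one projected point per centerline point
  the difference is far below the 5% validation band, but very coarse
  centerlines would understate it.
- DBLC is unsigned; a centerline crossing the mesh (non-physical, but
  possible in noisy inputs) is not flagged.
- The type Ib demarcation rule is the left-right mirror of the Ia wording;
  no independent anatomical source fixes it.
- Voxel-count volumetry carries discretization error that oscillates with
  structure size relative to spacing; sub-voxel structures are unreliable,
  and strict mode refuses tubes thinner than two voxels.
- The cohort simulator's exponential, proportional-hazards times and uniform
  marker ranges are conveniences; they are the null the statistics are
  validated under, not a claim about clinical PPVS dynamics.
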