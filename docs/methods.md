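# Methods

## Dose model

`brachyqa` computes absorbed dose to water around an HDR stepping source
with the TG-43U1 line-source formalism,

D(r, θ) = S_K · Λ · [G_L(r, θ)/G_L(r₀, θ₀)] · g_L(r) · F(r, θ),

and superposes dwell contributions weighted by dwell time (seconds / 3600 ×
dose rate in cGy/h). Assumptions inherited from the formalism: an unbounded
water medium, no inter-source or applicator attenuation, no transit dose
between dwells, and source strength as stated in the plan (no decay
correction between planning and delivery).

Geometry is carried in millimetres (the DICOM convention) and converted to
centimetres only inside the kernel. Doses are cGy per fraction; EQD2 tables
are Gy.

### Geometry factor

Off axis, G_L = β/(L·r·sinθ) with β computed as the angle between the two
vectors joining the calculation point to the ends of the active line
(`atan2` of cross and dot products — numerically stable at all angles). For
sinθ < 1e-6 the on-axis closed form (r² − L²/4)⁻¹ is used; the two branches
agree to better than 1e-4 relative at the switch, far below table
resolution. On-axis points with r ≤ L/2 are inside the source and raise an
error.

### Source tables

Tables are structured-text (YAML) documents carrying L, Λ, the g_L(r) grid
and the F(r, θ) matrix. Interpolation is linear in r for g_L and bilinear
in (r, θ) for F; TG-43 tables are dense enough that higher-order schemes
would only risk overshoot near the source. Lookups outside a table are
clamped to the nearest edge and emit one warning per call site — TG-43
tables define nothing beyond their range, and clamping is predictable.

Two tables ship with the package. `toy` has unit g and F, so closed-form
identities (dose rate = S_K·Λ at the reference geometry, inverse-square
behaviour in the small-L limit) hold exactly; most tests use it.
`ir192-generic` is a **synthetic, representative** Ir-192 table (L = 0.36
cm, Λ = 1.109 cGy h⁻¹ U⁻¹, g_L within ±1% of unity out to 6 cm, polar
anisotropy falling to ~0.57–0.77 with a mild cable-side asymmetry). Its
magnitudes are physically plausible for an mHDR-v2-class source but it is
not a manufacturer or consensus dataset; clinical use requires loading the
table for the actual source.

### Near-source handling

Grid voxels whose centre falls within half the active length of a dwell are
assigned that dwell's transverse-axis dose at the capsule radius instead of
a near-singular kernel value. These voxels lie inside the applicator lumen;
the cap keeps DVH tails finite without affecting tissue voxels. The number
of capped contributions is recorded in the dose-volume metadata.
Reference-point evaluation (`dose_at_points`) refuses points inside a
capsule instead of capping — a second check should never silently report a
capped point dose.

## Ring orientation reconstruction

Plans state dwell positions but not source orientations. For ring channels
the orientation is recovered in two steps:

1. **Plane and circle.** Every triple of dwell positions defines a candidate
   plane normal (all C(n,3) triples for n ≤ 12, else a deterministic stride
   subsample of 220 — ring channels rarely exceed ~20 dwells; triples whose
   triangle area is below 1e-6 mm² are rejected as collinear). The candidate
   minimizing the RMSE of point-to-plane distances wins. The circle centre
   and radius are then fitted to the positions projected into that plane by
   the algebraic (Kåsa) least-squares method. For exact data this equals
   fitting a sphere and intersecting it with the plane; for noisy data the
   in-plane fit is the better-conditioned choice.
2. **Tangents.** Each dwell is oriented along normal × (p − centre),
   normalized, with the sign chosen so the direction advances along the
   channel's delivery order (positive dot product with the chord to the next
   dwell; the last dwell uses its predecessor's chord).

Tandem and generic channels use the chord-chaining baseline: direction_i =
normalize(p_{i+1} − p_i), the last dwell reusing the previous direction.
This is also the comparison baseline for rings, where it deviates from the
true tangent by exactly half the angular step between dwells — the
quantitative form of the tangent method's advantage that the test suite
verifies for n ∈ {4, 8, 16, 36}.

Recovery accuracy under noise: over 100 seeded rings with position noise
σ ∈ {0.05, 0.1, 0.2} mm (reconstruction uncertainty scale), the fitted
normal and the tangents are within 1° of ground truth on average (the
acceptance script reports the measured values).

## Grids, DVH and criteria

Dose grids are regular, defined by origin (centre of the first voxel),
spacing and dimensions. In-plane spacing is selectable — 0.5, 1.0 (default)
and 2.5 mm are the standard options — and the slice spacing defaults to the
structure set's. Dose is evaluated at voxel centres with no supersampling,
so refining the grid never changes the value at a shared voxel centre and
grid-size effects on DVH parameters are purely a sampling phenomenon.

A voxel belongs to a structure iff its centre lies inside the slice's
polygon set under the even-odd rule (matplotlib path tests XOR-ed across
polygons, which handles annular applicator cross-sections). No
partial-volume weighting: rasterized volumes therefore depend on grid size,
which is exactly the mechanism a second check must expose when comparing
DVH parameters across grid resolutions. Contour slices are matched to the
nearest grid slice and dropped with a warning beyond half a slice spacing.

Dx% is the minimum dose to the hottest x% of the structure volume and Dxcc
the minimum dose to the hottest x cm³, both computed from the exact sorted
voxel doses with linear interpolation between adjacent sorted values at
fractional voxel counts — no histogram binning (exported curves are binned
at 1 cGy for plotting only). Dxcc with x exceeding the structure volume is
an error at metric level; the bundled-report path skips such metrics (small
organs legitimately have < 10 cc). The target is reported both with the
applicator voxels included and excluded (target AND NOT applicator).

Plan criteria default to HR-CTV D90% ≥ 550 cGy and D2cc < 460 (bladder) /
420 (rectum, sigmoid) cGy per fraction; "<" limits are strict. Criteria
referencing a missing structure or metric are reported unevaluable and fail
the overall check.

## EQD2

BED = nd(1 + d/(α/β)), EQD2 = BED/(1 + 2/(α/β)); α/β defaults to 10 Gy for
the tumour target and 3 Gy for bladder/rectum/sigmoid, overridable in
config. Multi-fraction totals convert each fraction at its own per-fraction
dose and then sum — the quadratic term acts within a fraction, so
converting the summed physical dose would be wrong. Voxelwise conversion of
whole dose volumes divides the engine's cGy by 100 at the boundary and tags
the result's units.

## Gamma analysis

γ(r) = min over evaluated points e of sqrt(‖e − r‖²/dta² +
(D_eval(e) − D_ref(r))²/(tol·D_norm)²). Defaults: 3%/3 mm, normalization to
the global maximum of the reference distribution, no low-dose threshold
(configurable; 10% is common clinically). γ ≤ 1 passes, with the exact
boundary counted as a pass; the pass test uses a 1e-9 relative guard so the
boundary convention survives floating point.

The search is exhaustive over evaluated grid points within a radius of
3·dta, and the radius grows adaptively to γ_best·dta whenever the best
candidate found is worse than the distance penalty at the current radius —
this makes the coarse search provably equal to a full-grid exhaustive
search, which the tests verify against an independent all-pairs oracle on
31×31 grids. One optional level of 10× sub-grid refinement (linear dose
interpolation around the best coarse point, on by default) bounds the
discretization of γ from above; an exact coarse agreement (γ = 0) skips
refinement.

Plane comparison extracts the ring's axis plane from a 3D volume: the plane
through the ring centre containing the ring normal, with the in-plane
lateral direction taken as the projection of the patient x axis (y if
degenerate). Values are trilinearly resampled; samples outside the volume
are NaN and excluded.

## Reference points

Reference-point doses are exact kernel evaluations at absolute coordinates,
never grid interpolations — matching how a plan's point doses are verified
against a TPS. Percent difference is 100·(check − TPS)/TPS, so a colder
second check yields negative values. The geometric points A and B
(ring centre + 20 mm along the tandem axis, ±20 mm and ±50 mm along the
lateral axis) are a convenience construction: the clinical definition is
anatomical (vaginal fornix), so verification against a TPS should use
user-supplied absolute coordinates. When the tandem runs along the ring
normal the lateral axis is not derivable from the fit alone; the workflow
uses the direction from the ring centre to the first ring dwell, and the
API accepts an explicit axis.

## Synthetic study conditions

The fixture generator emulates a re-optimized tandem-and-ring cervix
application: 8 ring dwells on a full 15 mm circle and 8 tandem dwells over
40 mm starting 5 mm above the ring centre, 18 s dwell times at S_K = 40700 U
(a nominal 10 Ci source), five fractions of 5.5 Gy. Dwell times were chosen
once so the synthetic plan, like a clinically re-optimized plan, meets the
standard criteria with margin (D90% ≈ 580 cGy at 1 mm). The phantom places
an ellipsoidal HR-CTV (semi-axes 22×22×28 mm) around the applicator with
offset ellipsoidal bladder, rectum and sigmoid, and an applicator ROI built
from the tandem cylinder and ring torus (tube radius 3 mm), contoured at 1°
vertex spacing on 2.5 mm slices.

What the phantom does **not** emulate: real anatomical shapes and
inter-fraction variation, contouring noise, TPS-specific rounding of dwell
data, or a Monte Carlo ground-truth dose. Passing tests therefore establish
the engine's internal correctness (against oracles and closed forms) and
the workflow's behaviour on realistic magnitudes — not agreement with any
particular clinical system, which requires site data.

Problem sizes used by the default test run and the acceptance script: the
full verification runs on a ~55×107×35-voxel grid at 1 mm (≈2×10⁵ voxels,
16 dwells), kernel oracle checks use 200 sampled points against 10⁵-segment
line integrals, and orientation statistics use 100 seeded rings. These
sizes make the whole suite complete in well under a minute while leaving
every code path exercised at clinical grid resolution.

## Numerical choices and edge cases

- On-axis branch switch at sinθ < 1e-6; collinearity rejection at triangle
  area < 1e-6 mm²; tangent undefined at the ring centre (error).
- Duplicate consecutive dwell positions make chained directions undefined
  (error naming the index).
- Empty dwell lists accumulate 0 cGy with a warning; empty structure masks
  are an error naming the ROI.
- DICOM RT Dose stores uint32 pixels scaled by DoseGridScaling; a write/read
  round trip reproduces values to within half a scaling quantum (the format
  cannot carry arbitrary floats bit-exactly).
- Fixture-text plan and structure files round-trip bit-exactly (floats are
  serialized with shortest-repr precision).
- Reports are deterministic for fixed inputs; timings go to the logger, not
  the report body.

## Limitations

Water-only TG-43 dose (no TG-186 model-based corrections, shielding, or
heterogeneity), ring/tandem orientation models only (no curved-tandem
splines or applicator libraries), no contour interpolation between slices,
no EBRT + brachytherapy EQD2 budgeting, and DICOM by file only.
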