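# Methods

## Scope and model class

`uvfield` evaluates direct UV radiation on the surface of a single **convex**
object. Convexity guarantees no macro-scale self-shadowing, so each surface
element interacts with each source independently and the whole field is a sum
of closed-form element–source terms — no ray tracing, no visibility queries.
Reflection, scattering, inter-object shadowing and near-field lamp models are
outside the model class. Two quantities are tracked everywhere:

* **fluence rate** `E'` (W/m²) — power through the point regardless of
  direction; its time integral is the **fluence** `F` (mJ/cm²), the dose
  metric used by surface-inactivation studies;
* **irradiance** `E` (W/m²) — cosine-weighted power onto the oriented
  surface; its time integral is the **dose** (mJ/cm²), what a flat detector
  or radiochromic film records. `E ≤ E'` always.

The shadow factor is the Heaviside step `H` of the incidence cosine with the
convention `H(0) = 1` (a grazing element counts as lit), and it is applied to
fluence rate as well as irradiance: an element facing away from a source
receives neither.

## Source models

**Directional** (collimated beam / sun): `E' = E'₀ H(c)`, `E = E'₀ c H(c)`
with `c = −n·u` (`u` the ray direction, `n` the outward surface normal).

**Point (LED)**: radiant intensity `I(θ) = I_max f(θ)` about the optical
axis, azimuthally symmetric; at distance `d`, `E' = I_max f(θ)/d² · H(c)`,
`E = E' c`. The relative-intensity profile `f` is a datasheet lookup table
(piecewise-linear by default, nearest-knot optionally); `f = 0` beyond the
last tabulated angle — no extrapolation. When a datasheet profile is not
available the bundled ideal cosine emitter is used, for which the
hemisphere-integral relation `P = I_max·π` holds; `i_max_from_power` inverts
`P = I_max ∫ f dΩ` by dense trapezoidal quadrature (20 001 nodes, exceeding
any datasheet resolution) for arbitrary profiles.

**Diffuse line (LSDE)**: a cylindrical lamp of power `P_o` and radiating
length `L` idealized as a line of diffuse differential emitters; a slice `dl`
radiates intensity `(P_o/(π²L)) cos γ dl`, `γ` the elevation from the plane
perpendicular to the lamp axis (the `π²` normalizes a cosine-in-elevation
emitter to unit total power). Only the **effective radiating segment** — the
clip of the lamp span `[−L/2, L/2]` against the element's tangent half-space
`n·(x−p) ≥ 0` — contributes; the plane test is linear in the axial
coordinate, so the clip is one interval (possibly empty or the full span).
With `t` the axial offset from the foot of the point's perpendicular, `D` the
point-to-axis distance and `ρ² = t² + D²`, integrating over the segment
`[u, v]` gives the closed forms

```
E' = P_o/(π² L D) · [ t/ρ ]ᵤᵛ
E  = P_o D/(π² L) · [ −c₁/(2ρ²) + c₂/(2D³)·(arctan(t/D) + tD/ρ²) ]ᵤᵛ
```

where the per-point constants are `c₁ = n·v̂` (axial slope of the incidence
cosine numerator) and `c₂ = −n·q` (its value at the foot, `q` the axis→point
perpendicular). Both forms are pinned by an independent quadrature oracle in
the test suite (composite Simpson on 10⁴ nodes over the clipped interval;
agreement ~1e-12 relative, asserted at 1e-6). For a centered, perpendicular,
lamp-facing detector the irradiance reduces exactly to the **Keitz formula**
`E = P_o(2α + sin 2α)/(2π²LD)`, `α = arctan(L/2D)`, whose inversion
(`keitz_power`) underlies lamp output measurement. Twin-tube compact lamps
are composites of two parallel line sources with equal power split and no
mutual occlusion (tube centers 14 mm apart, 129 mm arc by default).

**Degenerate inputs.** The models are far-field: points within
`d_min = 1e-6 m` of a point source's center or a line source's axis raise an
error rather than returning a large number — such configurations abort field
evaluation with element/timestamp context instead of silently zeroing.
Grazing line-source segments can produce round-off at the −1e-17 level; the
outputs are clamped at zero.

## Motion and time integration

Object motion is a list of key poses (4×4 rigid homogeneous transforms,
local → base) at strictly increasing normalized timestamps, 0 first, 1 last.
Evaluation timestamps are evenly spaced including both endpoints; within a
segment translation interpolates linearly and rotation by quaternion SLERP
along the shorter arc (scipy's implementation, which canonicalizes
quaternions — this supplies the antipodal sign correction and a deterministic
axis at the exactly-180° edge, where the arc is intrinsically ambiguous).
Interpolated rotation matrices are re-orthonormalized by SVD projection so
long pose chains stay rigid to ≤1e-10. Surface elements are transformed per
timestamp **from the original elements**, never chained, avoiding drift.

Fluence and dose are trapezoidal integrals of the rate matrices over actual
times (normalized timestamps × duration), exact for rates affine in time and
O(Δt²) otherwise; accuracy is controlled by the step count, not the
duration. Internal accumulation is SI (J/m²); reported units are mJ/cm²
(×0.1). A single-pose (static) exposure is handled as rate × duration.

## Inactivation and spectral weighting

The average germicidal power ratio `P_avg/P_o = ∫GF·G dλ / ∫G dλ` weights a
source's emission spectrum `G` by a pathogen's germicidal-factor curve `GF`;
quadrature is trapezoidal on the union of the two wavelength grids with
linear interpolation of both curves, and a monochromatic line bypasses
quadrature (the ratio is `GF(λ₀)` exactly — 1.0 for an ideal 253.7 nm
mercury line with `GF` normalized there). GF curves are user-supplied CSV
data; none are bundled as authoritative.

Dose-response uses `log₁₀(N/N₀) = −(F/α)^β` (Weibull; `α` in mJ/cm² is the
1-log fluence, `β` shapes shoulder/tailing) or `−kF` (Chick–Watson, `k` in
cm²/mJ; log₁₀ convention, consistent with published `k ≈ 5e-4` against
multi-log reductions at ~10³ mJ/cm²). Reciprocity is assumed: reduction
depends on fluence only, never on exposure time, which is appropriate for
the second-to-minutes exposures targeted here. Published parameter tables
for these models on chicken breast are shipped as a data frame
(`inactivation.TABLE1`) for reference; the mercury-lamp Weibull rows there
(α ≈ 0) are singular under the scale–shape form and are not used as ground
truth for it.

Fitting: Chick–Watson by closed-form regression through the origin; Weibull
by nonlinear least squares in `(log α, log β)` (positivity for free) with a
multi-start over `β₀ ∈ {0.25, 0.5, 1, 2}` and `α₀` at the median fluence,
keeping the lowest-cost converged solution. RMSE and R² are reported on the
fitted residuals (R² can be negative when a family underfits, as log-linear
fits to strongly shouldered data do), plus delta-method standard errors from
the Jacobian; a Monte-Carlo audit shows these SEs match the empirical
sampling spread, with 3-SE coverage at the nominal ~97–99%. Threshold maps
use `≤` on the signed log₁₀ value (−2.3 passes a −2.0 threshold) and report
both element-count and area-weighted pass fractions, since the mesh is only
quasi-uniform.

## Power estimation

A lamp's output is estimated from irradiance readings at multiple distances
(detector face to lamp midplane, fixed orientation facing the lamp center).
The model is linear in total power, so each reading yields
`P̂ᵢ = readingᵢ / unit-power modeled irradiance`; the estimate is the
arithmetic mean over distances — robust to distance-dependent model error —
and each reading's relative deviation from the mean-power curve is returned
for diagnostics. A single perpendicular centered reading of a single tube
reduces exactly to the Keitz inversion.

## Geometry handling

STL files (binary and ASCII) are parsed by trimesh; a byte-size pre-check
reports the offset where a truncated binary file ends. Vertices are welded
on exact coordinate equality, so both encodings of one model produce the
same welded geometry. File facet normals are trusted when they agree with
the right-handed winding normal (positive dot) and recomputed from winding
otherwise — files in the wild disagree. Facets with area < 1e-12 m² are
flagged degenerate and excluded from element extraction. Convexity is
verified by testing every vertex against every facet's supporting plane with
a default slack of 1e-6 m (discretization noise on cm-scale meshes);
violations are reported per facet. Surface elements are triangle centroids
with facet normal and exact triangle area; rigid transforms map positions by
the full transform and normals by the rotation block, preserving total area
to ≤1e-12 relative.

## Synthetic data and what the tests show

The fixture generators produce convex analytic meshes (box; icosphere at
subdivision 3, whose area is within 1% of `4πr²`) and seeded dose-response
observations from a chosen model with Gaussian noise in log₁₀ units
(σ = 0.1 by default in tests, typical of plate-count scatter). The shipped
light-environment presets are fixed study conditions: 20 twin-tube 2.5 W
mercury lamps over 1.5 m (25 W toward the base plane) and a 50 × 5 grid of
110 mW LEDs over 1.5 m × 0.2 m (27.5 W), both 0.1 m above the base plane;
end-to-end runs use 50 motion steps over 1200 s. Synthetic meshes lack the
irregular curvature and mesh-density variation of scanned food models, and
the cosine LED profile lacks datasheet side lobes, so passing tests
demonstrate correctness of the radiometry, interpolation, integration and
estimation machinery — not the fidelity of any particular lamp datasheet or
pathogen model to a real process. Problem sizes in the default suite
(≤1280 elements × 250 sources × 50 steps) were chosen so a full run stays
comfortably interactive on one core while still exercising every code path
at realistic scale.

## Known limitations

Single convex object; direct radiation only; far-field source models (no
ESDE/ESVE-style near-field cylinder treatment, no excimer-lamp angular
model); azimuthally symmetric LED profiles; no detector cosine-response
correction; no photoreactivation or time–dose reciprocity failure in the
inactivation layer (microscale surface shadowing is considered folded into
the empirical dose-response parameters).
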