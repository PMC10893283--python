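# Methods

## Geometry model and conventions

A scaffold is the sublevel set Ω = {x : φ(x) ≤ 0} of an implicit scalar
field: non-positive values are solid, the zero level set is the printed
surface, and the boundary counts as solid.  Every porosity computation in
the package shares this single predicate (`values <= 0`), so voxel
counting, Monte-Carlo estimation and mesh volumes are mutually
consistent.  Scaffolds are centered on the z-axis with z ∈ [−h/2, h/2];
all coordinates are mm, TPMS field values are dimensionless, and the
shell/envelope field is a signed-distance-like quantity in mm.

The gyroid and diamond fields use the standard trigonometric
approximations with spatial frequency τ (cycles/mm; unit cell 1/τ) and
level constant c.  Raising c shrinks the solid phase's complement — under
the solid-sublevel convention porosity *decreases* with c, which is the
sign check built into `PorosityFit`.

The solid-cylinder field is implemented as
max(√(x²+y²) − R, |z| − h̄).  A published variant of this function mixes
squared and linear length units (x² + y² − R²) and carries a sign-flipped
cap term that would empty the slab; the form used here is the standard
signed expression with the evidently intended zero set (the cylinder
boundary), a deliberate correction.

## Porosity calibration

Porosity of a periodic field over one full period cube is independent of
τ, so calibration is decoupled from the envelope: each family is
calibrated once at τ = 1 over [0, 1)³ and the fit reused for any pore
size.  Defaults: 9 level values c ∈ [−0.6, 0.6], Monte-Carlo n = 2×10⁵
points per value (binomial standard error ≈ 0.0011), fixed seed
20240472; all configurable.  The fitted line must be strictly monotone in
the measurements (otherwise the estimator noise is too high and the fit
is refused) and a residual RMS above 0.01 porosity units warns that the
linear model is strained on that range.  Measured gyroid coefficients are
m ≈ −0.324, b ≈ 0.499 (the intercept is pinned at ½ by the gyroid's odd
symmetry at c = 0, which doubles as a test anchor); diamond m ≈ −0.586,
b ≈ 0.500.

The pore-radius relation r = (1 − c)/(aτ), a = 4 (G) / a = 8 (D), is
taken with the multiplicative (1 − c) numerator: at c = 0 it gives the
standard quarter- (gyroid) or eighth-period (diamond) pore and shrinks as
c grows, consistent with falling porosity.  The alternative reading
1/(aτ(1 − c)) would grow with c and contradict that monotonicity.

Design solving is pure inversion — c = (ρ − b)/m, τ = (1 − c)/(ar) — and
refuses to extrapolate outside the calibrated c range.  Reaching 30 %
gyroid porosity needs c ≈ 0.62, so loop-closure checks across
ρ ∈ {0.3, 0.4, 0.5} calibrate over the wider c ∈ [−0.8, 0.8].

The cylindrical envelope crops the periodic field, so the porosity of the
finished part deviates slightly from the unit-cell value; this deviation
is *reported* (in `ScaffoldReport`) rather than calibrated away.  It is
small when several periods fit in the envelope (gyroid, r = 1 mm, 10 mm
cylinder: measured 0.408 vs target 0.400) and grows when the unit cell
approaches the envelope size (diamond at r = 1 mm has a ~12 mm cell —
under one period per part — and deviates by about +0.02); choosing a
smaller pore radius restores agreement.

## Shell hybridization

The tapered window Π(ξ; c) with sharpness s = 0.03 is exactly 0.5 at its
knee ξ = c, saturating to 1 inside and 0 outside within roughly ±10 % of
the knee radius.  The blend weight is the product of the radial window at
R̄ = R − t and the axial window at h̄ = h/2 − t.  Two orientations are
available:

* `shell_outside` (default): φ_h = γ·φ_TPMS + (1−γ)·φ_S — the TPMS
  governs the core (γ ≈ 1), the solid shell the rim and caps.  This is
  the physically coherent form for a shelled porous scaffold.
* `as_printed`: the literal transposed weighting γ·φ_S + (1−γ)·φ_TPMS,
  kept selectable for fidelity experiments.  Taken literally it places
  the solid field in the core and the TPMS at the rim — the opposite of a
  shelled scaffold — which is why it is not the default.

Because the TPMS values are O(1) and the shell field is mm-scaled, the
shell component is divided by the thickness t before blending; only the
zero set and near-boundary gradient matter, and this keeps either term
from dominating the transition band.  The blended field is clamped to
void outside the envelope cylinder via max(φ_h, φ_env), which preserves
the sign everywhere inside.  With t = 0 the blend degenerates to the TPMS
clamped to the envelope, which is also its sharp-window limit.

## Meshing and measurement

Fields are sampled at voxel centers (unbiased for symmetric fields) on a
uniform grid covering the envelope plus one padding voxel per side; the
padding layer is forced void so every extracted isosurface closes.
Marching cubes (scikit-image) extracts the zero level set; the raw
triangle soup is vertex-merged and cleaned of zero-area slivers
(trimesh `process=True, validate=True`) — without this, fine grids yield
non-manifold edges — and oriented so the enclosed volume is positive.

Default resolution is max(10, 8τ, 20/t) voxels per mm: at least 8 voxels
per TPMS period, 20 across the shell, and a 10 voxels/mm floor so that
volume and pore-size measurements on coarse-period designs (the reference
gyroid has a 5.8 mm cell) stay inside ±2 porosity points.  Grids are
capped by a voxel budget (default 8×10⁷) and the error message reports
the admissible resolution.  The resolution used is echoed in the report.

Measured quantities: solid volume from the signed-volume sum of the
watertight mesh (refused, with the flag set, for non-watertight input);
porosity as 1 − solid/envelope against the *analytic* envelope cylinder;
bounding box; connected-component count (disconnected solid islands are
surfaced, not removed — they matter for printability); and pore radius as
the largest inscribed sphere of the interior void phase — the maximum of
the Euclidean distance transform over void voxels inside the envelope,
with everything outside the envelope treated as exterior.  This is a
measurement protocol choice: the design relation r = (1−c)/(aτ) defines
the target, and the inscribed-sphere metric is how the finished geometry
is audited against it (the gyroid channel admits a sphere ~10 % wider
than the nominal design radius, hence the measured 1.13 mm for a 1.0 mm
design).  STL files are unitless; the JSON report records mm.

The straight-pore reference scaffold (cylinder pierced by an axis-aligned
square lattice of straight channels, channels at lattice-cell centers) is
provided for comparison; its lattice layout is this package's choice and
is stated in the report it produces.

## Characterization math

* Vinyl conversion C_v = 1 − A_printed/A_liquid from integrated C=C band
  areas (default window 1620–1660 cm⁻¹).  Normalization is by the
  liquid-resin band area only.  A printed area exceeding the liquid area
  is an integration inconsistency and raises, never clamps.
* Band areas are trapezoids above a straight baseline through the window
  endpoints; net-negative areas report 0 with a warning.
* Stretch λ = (L₀+Δ)/L₀ with compressive Δ negative, so λ < 1; strain is
  reported as 1 − λ (positive in compression).  Stress σ = F/(πR₀²) is in
  MPa for F in N and R₀ in mm.  λ ≤ 0 (crush-through) raises.
* Young's modulus: OLS slope over the leading strain window 0.5–2.5 %,
  shrunk from the right until R² ≥ 0.995; if no admissible window with
  ≥ 10 points reaches the floor, the toe region is flagged non-linear.
  Fracture is the first sample whose stress falls > 20 % below its
  running maximum; the preceding peak is reported as the fracture point.
* Printability gates: viscosity ≤ 5×10³ mPa·s (inclusive), contact angle
  < 30° (strict), Bond number Bo = Δρ·g·L²/γ < 1 (strict) with
  g = 9.81 m/s².  The Bo expression is the standard definition (the
  threshold is quoted in the literature without a printed formula), and
  the boundary semantics are this package's documented convention.  Each
  gate is evaluated independently; missing inputs are reported as "not
  evaluated", not failed.

## Synthetic data

Two generators make every characterization routine testable without
instrument data: a Gaussian C=C band (amplitude 1, center 1645 cm⁻¹,
σ = 8 cm⁻¹, 601 samples over 1500–1800 cm⁻¹, optional linear baseline and
additive noise) with closed-form area Aσ√(2π); and a compression curve
(default E = 1 MPa, L₀ = 10 mm, R₀ = 5 mm, yield at 8 % strain, fracture
at 15 %, 400 samples to 20 %, 1 % multiplicative stress noise) shaped as
elastic line → one-third-slope plateau → collapse to 10 % of peak.  These
emulate the *shape* of real records, not their artifacts: no toe-in from
platen seating, no detector spikes or fluorescence background curvature,
no viscoelastic rate dependence.  Passing tests therefore demonstrate the
extraction math, not robustness to instrument pathology.

## Problem sizes and determinism

Default runs are desk-scale: calibration costs 9 × 2×10⁵ field
evaluations (~0.3 s), the reference 10 mm scaffold samples a ~102³ grid
and meshes in ~2 s, and the full test suite runs in well under a minute.
All randomness flows through explicit seeds (package default 20240472);
per-point calibration seeds are derived as seed + index.  Fixed seeds
give byte-identical STL output and identical JSON reports.

## Known limitations

* Only gyroid and diamond families; no graded or anisotropic τ/c fields,
  no non-cylindrical envelopes, and a single shell per part.
* The linear ρ(c) model degrades beyond |c| ≈ 0.8; the fit warns via its
  residual RMS but a nonlinear model is out of scope.
* Envelope-crop porosity deviation is reported, not compensated; designs
  whose unit cell approaches the envelope size will miss tight porosity
  targets (see the diamond example above).
* The inscribed-sphere pore radius is resolution-limited (half-voxel
  bias) and summarizes the pore network by its widest point, not a size
  distribution.
* No slicing, supports, cure-depth or photopolymerization simulation, and
  no prediction of measured mechanical properties — the compression
  module processes recorded curves only.
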