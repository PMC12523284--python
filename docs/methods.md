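# Methods

This note documents the model, its numerical treatment, the synthetic
twin that stands in for a real monitoring campaign, and the design
choices made where the problem left them open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Physical model and assumptions

The grain bulk is a continuous, isotropic, homogeneous porous medium;
the interstitial air is incompressible; grain and air are in local
thermal and sorption equilibrium; metabolic (respiration) heat is
excluded, so the only latent term is sorption/desorption heat. The
model is solved on a 2-D vertical cross-section of a flat warehouse —
the plane is where monitoring practice draws its maps, and a 2-D
section captures the wall-to-wall asymmetries that drive the dynamics.

**Flow.** Natural convection in a grain bulk is creeping flow, so Darcy's
law with Boussinesq buoyancy applies: `u = m(−∇P + ρ₀gβ(T−T₀)ẑ)` with
mobility `m = K/(φμ)`. The buoyancy term acts along gravity only (the
tensor subscript in the momentum balance is read as a Kronecker delta
selecting the vertical; no other reading is dimensionally coherent).
`φ` (the equivalent kernel diameter expressed in mm) is kept inside the
drag denominator as an effective-resistance calibration; with the
Kozeny–Carman permeability `K = 4.8·10⁻⁸ m²` the resulting mobility
gives peak interstitial velocities of order 10⁻⁴ m/s for a few-degree
horizontal contrast — the magnitude reported for warehouse-scale
natural convection. Incompressibility turns the velocity field into a
pressure Poisson problem with `∂P/∂n = buoyancy·n` (no-normal-flow)
boundaries; the all-Neumann system is pinned at one reference cell.

**Energy.** Grain-side storage `ρ_b C_b ∂T/∂t` with the moisture-dependent
specific heat, conduction with the temperature-dependent conductivity
`k_b(T)`, air-side advection `ρ_a C_a u·∇T` (three orders of magnitude
weaker per metre than grain storage, which is why grain bulks are so
sluggish), and sorption heat `h_fg ρ_b ∂W_g/∂t` lagged from the previous
moisture step.

**Moisture.** Dry-basis moisture `W_g` is conserved with three transport
routes: down-gradient vapor diffusion (`D_M = D_eff σ`),
temperature-gradient cross-diffusion (`D_T = D_eff ω`, moving moisture
from warm to cold — the mechanism behind moisture accumulation in cold
pockets), and convective vapor transport with the `σ/(R_v T)` and
`ω/(R_v T)` factors. Vapor-pressure gradients are converted to vapor
density by `1/(R_v T)` inside the fluxes; the printed composition
`D_eff = D_v ε τ_b R_v` is dimensionally inconsistent and the standard
porous-medium reduction `D_eff = D_v ε / τ_b` is used instead (the
literal form remains available behind `MaterialParams(paper_literal=True)`,
as do the literal air-property correlations, which give unphysical
values at storage temperatures and are replaced by `C_a = 1.006`
kJ/(kg °C), `k_a = 0.026` W/(m °C) by default).

**Sorption closure.** The isotherm is not specified by the source
problem; the Modified Chung–Pfost equation for shelled maize
(`A = 312.31, B = 16.958, C = 30.205`; T in °C, moisture dry-basis
decimal) is adopted because it is the ASAE-standard maize isotherm and
reproduces the expected interstitial humidity (≈70 % at 14 % w.b.,
25 °C). Saturation pressure is the Magnus formula. Both partials
`σ = ∂p/∂W_g` and `ω = ∂p/∂T` are analytic; tests verify them against
central finite differences.

**Envelope forcing.** The exterior drives the bulk through sol-air
temperatures `T_sa = T_amb + αI/h_out` per face and fluxes
`q = U_face (T_sa − T_surface)` with `U_wall = 0.62`,
`U_roof = 1.25 W/(m² °C)`. The radiation model is a half-sine day
(sunrise 5 h, sunset 19 h, peak 800 W/m²) scaled by per-face
orientation factors (south 1.0, north 0.3, east/west 0.6, roof 1.0) —
a deliberate simplification of solar geometry that encodes the one
fact that matters at this scale: the south wall of a northern-hemisphere
warehouse receives several times the daily insolation of the north
wall. `α = 0.6` and `h_out = 15 W/(m² K)` are typical masonry values.
The floor is adiabatic (ground coupling unspecified); the grain surface
exchanges with roof-moderated air through the roof U-value and a
5 W/(m² K) film in series. The parametric ambient model is
`T = mean + drift·t/30 d + amplitude·cos(2π(t − t_peak)/24 h)`, i.e.
the daily maximum falls at `t_peak` (15:00); a supplied (time, °C)
series is interpolated piecewise-linearly instead when given.

## Numerics

Uniform cell-centered finite volumes, default spacing 0.1 m (area
quantization ≤ 0.01 m² per cell), default step 600 s, operator split
per step as flow → energy → moisture → humidity (first order in time,
adequate at these time scales).

* Conduction is backward-Euler implicit with harmonic-mean face
  conductivities; the sparse factorization is cached and rebuilt only
  when the temperature field drifts more than 0.5 °C from the state at
  assembly (the conductivity changes ~0.2 %/°C, so the lag is
  negligible). Robin (envelope) conductances sit on the matrix
  diagonal, with the time-varying sol-air temperature on the right-hand
  side; Dirichlet sides use half-cell conductances. Boundary exchange
  is applied at the boundary-cell center — a first-order treatment
  whose effect on the day-7 plane mean halves with the spacing (checked
  0.1 m → 0.05 m in the tests).
* Heat advection is explicit first-order upwind in conservative flux
  form; a CFL monitor substeps automatically (logged) if the effective
  advection speed ever demands it.
* The moisture equation is advanced explicitly in conservative flux
  form with face-averaged coefficients and upwinded scalars. Its
  diffusion number at the default resolution is ~10⁻⁴, so explicit
  integration is unconditionally benign, and the flux form makes the
  closed-domain moisture budget exact to round-off — which the tests
  assert at 10⁻¹⁰ relative over 100 steps. (The configuration names an
  implicit diffusion scheme; it is applied to the energy equation,
  where it matters, and deliberately not to moisture, where it would
  cost per-step reassembly for no stability benefit.)
* The pressure Poisson operator is constant and factorized once per
  mesh; each flow solve is a back-substitution. Discrete divergence is
  checked after every solve (relative tolerance 10⁻⁸).
* `W_g` is clipped to the isotherm validity range [0.05, 0.35] with a
  logged warning; `M` and `RH` are resynchronized after every step.

## Initialization

The day's readings are interpolated with a cubic RBF (`φ(r) = r³`,
degree-1 polynomial tail, orthogonality side conditions — the standard
well-posed form; pure interpolation, no smoothing) onto the mesh. The
loop then alternates: one hour of thermal-only relaxation under the
actual boundary forcing; comparison of the relaxed model at the sensor
positions (bilinear sampling) with the readings; a nudge of the field
by λ = 0.5 times the RBF-interpolated mismatch. Convergence is the
maximum sensor mismatch falling below 0.1 °C, capped at 25 iterations;
non-convergence is reported, not raised. The candidate is clipped to
[min reading − 2 °C, max reading + 2 °C] to guard against cubic-RBF
overshoot between sensors. Thermal-only relaxation per iteration is a
choice: temperature is the only observed field, and the flow/moisture
responses over one hour are negligible. Moisture is initialized
uniformly at the configured sampling value (14 % w.b. default) and
humidity from the isotherm — the cable grid observes temperature only.

Because the RBF already reproduces every reading exactly and one hour
of relaxation barely moves interior temperatures, the loop typically
converges at the first check with a residual near the sensor noise;
the nudging iterations engage when the model and the readings disagree
(e.g. a mis-specified boundary state), and the residual history is
monitored for non-monotonicity.

## The synthetic twin

Real warehouse campaigns of this type are not published, so the study
conditions are a synthetic twin chosen once:

* **Geometry/plane:** 24 m × 6 m XOZ section (fill height 6 m is given;
  plan dimensions are not, 24 m is a typical flat-warehouse span).
* **Sensor layout:** 4 layers × 78 sensors (13 columns × 6 rows) in a
  24 m × 18 m plan, layers at 0.75/2.25/3.75/5.25 m — the tightest
  regular grid consistent with the ≤ 5 m / ≤ 1.5 m spacing rule. One
  daily sample per sensor at 00:00; 30 days → 9360 records. Sensor
  noise 0.1 °C; optional sentinel-code injection.
* **Ground truth:** uniform 16.8 °C background (plus 0.05 °C/day
  seasonal drift in the analytic campaign field) with three Gaussian
  cold cores: south-adjacent (0.9, 2.0) m, σ = 1.1 m, 3.0 °C deep;
  central (12, 3) m, σ = 2.2 m, 3.5 °C deep; north-adjacent
  (23.1, 4.0) m, σ = 1.1 m, 3.0 °C deep. Initial sub-15 °C area
  ≈ 28 m². The wall-adjacent cores are shallow and lie within a metre
  of their walls because grain conduction is slow
  (α ≈ 10⁻⁷ m²/s, one-month penetration depth well under a metre): a
  cold pocket can only disappear within a storage month through its own
  in-place decay plus envelope heat, so month-scale disappearance —
  with the south pocket dying first by virtue of the insolation
  asymmetry — requires exactly this configuration. The central core is
  larger and outlives the month.
* **Weather:** August continental defaults (mean 24 °C, amplitude 6 °C,
  afternoon peak; irradiance model above).

What the twin does **not** emulate: respiration and bio-heating, sensor
drift/ageing, 3-D effects (end walls, plan-wise convection), ground
coupling, rain/long-wave radiation, and the head-space air layer as a
resolved domain. Passing twin tests therefore demonstrates that the
pipeline recovers and propagates fields correctly under the stated
physics — not that the physics is complete for any particular real
warehouse.

## Diagnostics

Low-temperature zones are 4-connected components of the sub-threshold
(15 °C) mask; diagonal-touching pockets count separately. Areas are
measured by marching-squares contours of the threshold level, assembled
into polygons, clipped to the physical domain and differenced against
any warm holes (shapely) — sub-cell accuracy is required for area
discrepancies far below one cell. Components smaller than 0.05 m² are
discarded as single-node noise. Whether published zone areas come from
contour integration or pixel counting is not stated; contour
integration is chosen and documented here.

PSNR is `10·log₁₀(peak²/MSE)`, infinite exactly when the images are
identical. SSIM is the mean local structural similarity with a Gaussian
window (σ = 1.5, 11 × 11 support), stabilizers K1 = 0.01, K2 = 0.03.
Both are computed on deterministically rendered 8-bit grayscale
contour-band maps (fixed 1 °C level set from 10 to 35 °C, band index
spread over 0–255), so map comparisons are bit-reproducible; an
elaborate plotting pipeline would add nothing the metrics can see.

## Problem sizes and determinism

The default twin runs 31 days at 0.1 m / 600 s on one CPU in about a
minute; the test suite uses the full-resolution twin for the
acceptance-style checks and reduced meshes (0.2 m, shorter horizons)
for unit physics. All randomness (sensor noise, fault injection) flows
from a single integer seed; two runs with the same configuration are
bitwise identical, which the manifest content hash asserts.

## Known limitations

* First-order operator splitting and upwinding; no turbulence or
  compressibility (excluded by assumption), no 3-D geometry, silos, or
  partially filled bins.
* The thermal-conductivity correlation is guarded to [−10, 60] °C: the
  printed quadratic changes sign near −14.5 °C, so winter campaigns
  near that bound would need a different closure.
* Sorption hysteresis and variety-specific isotherms are not modeled;
  the isotherm is configurable.
* The nudging loop is one admissible realization of
  initialize-and-iterate; ensemble or variational assimilation is out
  of scope.
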