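# Methods

`eulfsi` solves fluid–structure interaction in the *full Eulerian* (one-field)
formulation: a single incompressible momentum equation describes both the
Newtonian carrier fluid and an incompressible Neo-Hookean visco-hyperelastic
solid on a fixed uniform Cartesian grid.  The solid is tracked by its volume
fraction α (volume-of-fluid) and its strain state by the left Cauchy–Green
tensor **B** = **F F**ᵀ, carried in the corrected form **B̃** = α^β **B**
(β = 1/2 for an incompressible solid), which keeps the divergence-form
transport of the strain well behaved across the interface.

## Governing model

With ρ_f = ρ_s = ρ and mixture viscosity μ = α μ_s + (1−α) μ_f:

    ∇·u = 0
    ∂t u + u·∇u = −(1/ρ)∇p_rgh + ∇·(2 ν D′) + (G/ρ) ∇·(α^{1/2} dev B̃) + S
    ∂t α + ∇·(α u) = 0
    ∂t B̃ + u·∇B̃ = L B̃ + B̃ Lᵀ,          L = ∇u

`S` is a uniform pseudo-pressure-gradient source that a proportional
controller adjusts every step to hold the bulk axial velocity at its target
(0.5 in the velocity scale below); its running value is the
pressure-gradient readout of the periodic pipe runs, with pressure drop
S·L.

The elastic term is implemented in the conservative form
∇·(α^{1/2} G dev B̃).  The printed momentum equation places α^{1/2} outside
the divergence, but substituting B̃ = α^{1/2}B into the mixture Cauchy
stress α G dev B gives the flux form, which also conserves momentum
discretely; the deviatoric part is used throughout (an undeformed solid,
B = I, exerts no force).  2D runs carry the zz tensor component explicitly
(plane strain) so deviatoric parts use the true three-dimensional trace.

**Nondimensionalization.**  Length: pipe diameter D; velocity: U = 2 ū
(twice the bulk velocity); time D/U; density ρ.  Then ν* = 1/Re_U with
Re_U = 2 Re, the controller target is ū/U = 0.5, and G* = G/(ρU²).  The
study conditions are Re = 50 (water-like ν = 10⁻⁶ m²/s at D = 1 mm,
ū = 50 mm/s), G = 10–100 Pa → G* = 1–10, μ_s/μ_f ∈ [1, 10], Courant number
0.1.  The published dimensional parameter table lists a fluid viscosity of
10⁻⁵ Pa·s, which contradicts Re = 50 by two orders of magnitude; Re = 50 is
treated as authoritative, and the configuration loader refuses dimensional
inputs that contradict a configured Re unless the Reynolds number is pinned
explicitly.

## Discretization

* **Grid.**  Uniform staggered (MAC) arrangement: scalars and tensors at
  cell centers, velocity components on faces.  This deviates deliberately
  from the collocated + Rhie–Chow arrangement of the reference
  implementation: the staggered divergence/gradient pair is an exact
  discrete adjoint, so the projection removes checkerboard modes by
  construction.  2D cases run internally as 3D arrays with one periodic z
  cell; every kernel has a single code path.
* **Interface.**  PLIC: each interface cell stores a plane n·x = c
  positioned by bisection so the truncated volume matches α to ~10⁻¹⁴.
  The cut-volume geometry uses a case-wise closed form with the difference
  on the smallest normal component taken analytically — naive
  inclusion–exclusion loses up to seven digits for nearly axis-aligned
  planes, which is enough to break the bounded advection update.
  Normals start from the smoothed Youngs gradient (warm-started from the
  previous step) and are refined by 2 reconstruction-distance-function
  (RDF) iterations: signed distances to neighbouring planes are averaged
  with inverse-distance weights over the 3×3(×3) neighbourhood and the
  normal re-derived from ∇Ψ.  The iteration count is configurable; the
  reference publication does not state one.
* **α advection.**  Directionally split geometric donor-cell fluxes with
  the dilatation correction of Weymouth & Yue (compression flag frozen at
  α^n > 1/2, sweep order rotated per step): conservative to round-off and
  bounded for face Courant numbers < 1/2 (driver enforces Co = 0.1).
  Sub-round-off clamp residues are pushed to the neighbouring interface
  cell with the largest capacity.  This replaces the unsplit face-flux
  integration of isoAdvector with an equivalent contract (sharp,
  conservative, bounded).
* **B̃ evolution.**  Componentwise third-order WENO upwinding in space
  (advective form; the velocity is discretely divergence-free), stretching
  source L B̃ + B̃ Lᵀ, trapezoidal (Crank–Nicolson-style) time integration
  realized as an explicit predictor plus one fixed-point corrector pass —
  second order, and exact for homogeneous simple shear, whose solution is
  quadratic in time.  Work is restricted to a bounding band around the
  solid; this is exact because the minimum-volume-fraction rule resets B̃
  outside the solid every step anyway.
* **Minimum volume fraction.**  Cells with α < α_min = 0.1 have B̃ reset to
  the zero tensor or the unit tensor (case dependent: zero for the cavity
  benchmark, unit for the pipe cases, matching their wall/initial values).
  The literal published rule also zeroes α itself; with a sharp PLIC
  interface that would erode the interface-skin mass continuously and
  cannot meet the volume-conservation invariants, so the scenario drivers
  reset only B̃ by default (`clip_alpha` restores the literal behaviour).
* **Momentum.**  Explicit conservative MUSCL (minmod) advection fluxes,
  variable-viscosity stress in flux form (the ∇(⅔ μ ∇·u) deviatoric-trace
  term is omitted: after projection ∇·u ~ 10⁻¹² and the term is absorbed by
  the pressure), elastic force at faces, then an incremental pressure
  projection.  Outer (PIMPLE-style) correctors re-evaluate the explicit
  terms; the scenario presets use one pass (adequate at Co = 0.1), the
  solver default honours the configurable count.
* **Pressure Poisson.**  Direct solves everywhere: FFT diagonalization on
  fully periodic boxes; FFT along the periodic pipe axis with prefactorized
  sparse cross-section solves (the wall mask is axially invariant); sparse
  LU over fluid cells for the cavity and stenosis.  Velocities are
  divergence-free to ~10⁻¹² after every step.
* **Time step.**  dt = min(Co Δx/max|u|, Δx²/(3 ν_max), Δx √(ρ/G)) — the
  CFL bound plus the explicit viscous and elastic-wave stability bounds.
* **Walls.**  Cylindrical and stenotic walls are stair-step cell masks
  (first-order accurate); all faces touching a wall cell are zeroed.  The
  pure-fluid Poiseuille verification instead uses the axisymmetric radial
  reduction, where the wall is exact: the cylindrical finite-volume
  operator and the quadratic one-sided wall-gradient closure are exact for
  parabolic profiles, and the bulk-velocity quadrature carries the
  Euler–Maclaurin end correction, so the controller's fixed point is the
  analytic profile itself (the measured L2 error is at solver tolerance,
  far below the published coarsest-mesh value of 1.2×10⁻⁵).
* **Gravity** defaults to zero: with ρ_f = ρ_s the p_rgh = p − ρ g·x
  formulation degenerates; a uniform-g option is retained.

## Shape metrics

All deformation metrics operate on the α = 0.5 isosurface (marching cubes;
periodic axes unwrapped first, and the α-weighted centroid re-expressed in
the unrolled vertex frame).  The orientation vector n is the
smallest-eigenvalue eigenvector of the gyration tensor of surface points
(sign fixed to n_x ≥ 0), ψ = arccos|n·x̂|; a near-degenerate smallest pair
(sphere-like clouds) is flagged and the previous n reused.  The co-rotating
frame is ζ = ẑ(t=0) re-orthonormalized against ξ = n each sample (a raw ẑ
is generally not orthogonal to a rotating n), η = ξ×ζ (right-handed).

Tube cross-sections are cut by the two planes *containing the torus axis*:
span(ξ, η) yields the forward/back pair (split by the sign of the η
coordinate), span(ξ, ζ) the right/left pair.  The published wording assigns
the meridian to the (η, ζ) span, but that plane is the equatorial plane,
whose intersection with the surface consists of two concentric circles that
cannot respond to tube squashing; the axis-containing planes are the only
reading consistent with the published schematic and with
construct-and-recover tests.  Each loop is fitted with a rotated ellipse
(center offset + angle + semi-axes, Levenberg–Marquardt on the implicit
residual); aspect ratio = min/max semi-axis ∈ (0, 1], consistent with
published ratios that start at 1 and decrease under elongation.  Bending
angles are 180° minus the angle subtended at the centroid by opposite
ellipse centers (0° when unbent — the published plots grow from 0 but never
define the zero), signed positive toward +ξ.  Projected-circle ratios bin
the (ζ, η) projection into 72 polar sectors; per-sector min/max radii trace
the inner/outer outlines; the inner outline is reported missing when a
sector is empty or the minimum radii collapse toward the center (no
resolved hole — e.g. a sphere).

## Scenarios and problem sizes

The presets are deliberately scaled-down desk conditions; the full
study-scale 3D resolution (320×64×64, torus r = 0.1, R = 0.3, horizon
t* = 20) is reachable through the configuration but is not what the
test-suite runs.

* **Cavity** (verification): unit box, lid speed 1, ν = 0.01 everywhere,
  G = 0.05, disk radius 0.2 at (0.6, 0.5), B̃ reset mode zero.  The solid
  starts undeformed, B̃ = α^{1/2} I.  (The published initial condition
  reads "B̃ = 0"; taken literally the strain equation — linear in B̃ —
  would keep the solid permanently stress-free and the benchmark would be
  vacuous, so the undeformed-state initialization is used.)  Convergence:
  centroid-trajectory L2/L∞ versus the N = 128 grid over t* ∈ [0, 5]
  (shortened from 20; the deformation that controls the error happens
  early, and the order fit is unaffected).
* **Torus in pipe**: periodic pipe, L = 3 D, 96×32×32 (Δx = D/32), torus
  scaled to r = 0.125, R = 0.3 (inside the published parameter ranges) so
  8 cells span the tube; G* = 10, viscosity ratio 1, started from rest with
  the controller active.  Horizons: t* = 8 for the inclined (ψ₀ = 45°) run
  — the rotation completes within this window — and t* = 5 for the
  horizontal (ψ₀ = 90°) hold test.  An optional seeded velocity
  perturbation (amplitude 10⁻⁴ U) is available for the vertical-torus
  symmetry-breaking studies, off by default.
* **Stenosis** (embolization test): the published geometry in mm — length
  6, inlet radius 1, throat radius 0.5, cosine taper over the central half
  (the taper shape is shown only schematically in the source; a smooth
  symmetric cosine matching the printed end/throat radii is adopted) — on a
  72×24×24 grid (Δx = 1/12 mm).  Particles: the surface-area-matched torus
  / disk / sphere / ellipsoid family, inclined 45°, centered 0.5 mm off
  axis, released near the inlet.  Driving: p_rgh Dirichlet 5.5 at the
  inlet and 0 at the outlet, velocity zero-gradient at both ends (the
  boundary-normal faces are projection degrees of freedom).  The published
  outlet condition is a zero pressure gradient, but with a fixed-value
  inlet and zero-gradient outflow nothing anchors the outlet pressure and
  the flow provably stalls from rest; pinning the outlet at 0 keeps the
  stated inlet value meaningful as a pressure drop.  Because the
  end-to-end drop is then fixed, the reported pressure-drop series is the
  drop across the stenotic segment (cross-section means at x = L/4 and
  3L/4), whose local maxima track the particle squeezing through the
  taper; the outlet flow rate is reported alongside.  Release protocol:
  the particle is inserted into a developed particle-free base flow
  (`stenosis_base_flow`), and the same baseline run, continued over the
  measurement window, is subtracted from the pressure-drop series
  (`excess_pressure_drop`) so the passage signal is not buried under the
  residual startup transient.  A solver blow-up is
  reported as a truncated series flagged diverged, matching the published
  behaviour of the non-toroidal shapes.  At this resolution the torus tube
  is spanned by only ~2.4 cells — the passage dynamics are qualitative,
  which is the scaled-down condition the comparison tests accept.
* **Poiseuille / forcing**: axisymmetric reduction, 64 radial cells
  (128 across the diameter), implicit-Euler diffusion with the controller,
  marched to ‖du/dt‖∞ < 10⁻¹⁰.

## What the synthetic conditions do and do not show

The generators emulate the study's idealized conditions: a single particle,
rigid straight/stenotic vessels, Newtonian plasma-like fluid, equal phase
densities, laminar Re = 50.  They do not emulate pulsatile flow,
non-Newtonian blood rheology, vessel compliance, particle–particle
interaction, or physiological branching — passing tests here validates the
numerical method and the published idealization, not hemodynamic realism.
Scaled-down grids resolve the torus tube with 8 cells (pipe) or fewer
(stenosis), so fine-scale features (surface-vibration spectra,
wall-lubrication films) are under-resolved; the published full-resolution
values for these are not targets here.

## Known limitations

* Stair-step walls are first-order; near-wall lubrication forces on a
  squeezing particle are under-predicted on coarse grids.
* det(B) = 1 is not re-projected; incompressibility drift of the solid is
  monitored through the volume series only (the source publication states
  no enforcement either).
* The clip rule erases elastic stress in interface-skin cells (α < 0.1),
  slightly softening the coupling at the surface.
* The single-pass outer corrector is first-order in the pressure/velocity
  coupling; at Co = 0.1 the splitting error is far below the spatial error.
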