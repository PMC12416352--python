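# eulfsi

Full Eulerian fluid–structure interaction for deformable embolic particles
in pipe flows.

Transcatheter arterial embolization delivers micro-particles through a
catheter to occlude target vessels; how a particle's shape and
deformability control its transport, deformation and the pressure drop it
causes is a computational-hemodynamics question.  `eulfsi` implements the
one-field (Eulerian–Eulerian) FSI method for this problem: an
incompressible Newtonian fluid and an incompressible Neo-Hookean
visco-hyperelastic solid share a single momentum equation on a fixed
Cartesian grid,

    ∇·u = 0,
    ∂t u + u·∇u = −(1/ρ)∇p_rgh + ∇·(2ν D′) + (G/ρ)∇·(α^{1/2} dev B̃) + S,

with the solid tracked by a volume fraction α (geometric VOF with PLIC
reconstruction and RDF-refined interface normals) and its strain by the
corrected left Cauchy–Green tensor B̃ = α^{1/2} B, advected with a WENO3
scheme.  A uniform forcing S is controller-adjusted to hold the bulk
velocity of periodic pipe flows at its target.  The package also provides
the particle-geometry constructors (torus / disk / sphere / ellipsoid with
surface-area matching), the deformation metrics used to analyze a
transported torus (orientation angle from the gyration tensor,
cross-section ellipse fits, bending angles, projected-circle aspect
ratios), and the verification and embolization scenarios: lid-driven
cavity FSI, forced Hagen–Poiseuille pipe, torus-in-pipe transport, and a
stenotic-pipe embolization test.

See `docs/methods.md` for the discretization and the scaled-down study
conditions the test suite runs.

## Worked example

Forced laminar pipe flow on the axisymmetric reduction, with the mean-flow
controller holding the dimensionless bulk velocity at 0.5 (Re = 50):

```python
>>> from eulfsi import AxisymmetricPipeFlow
>>> flow = AxisymmetricPipeFlow(n_radial=64, re=50.0, target_mean=0.5)
>>> res = flow.run_to_steady(tol=1e-10)
>>> print(f"bulk = {res.bulk:.6f}  S = {res.S:.6f}  L2 = {res.l2:.3e}")
bulk = 0.500000  S = 0.160000  L2 = 4.764e-11
```

The steady forcing S equals the analytic Poiseuille pressure gradient
16/Re_U = 0.16 (Re_U = 2·Re is the Reynolds number on the U = 2ū velocity
scale), and the L2 error of the axial velocity along a diameter against
u(y) = 8ū·y(1−y) is at solver tolerance.

A deformable torus in the periodic pipe (scaled-down preset, ψ₀ = 45°):

```python
from eulfsi.scenarios import pipe_config, run_torus_in_pipe
res = run_torus_in_pipe(pipe_config(psi0_deg=45.0, t_end=8.0))
m = res.metrics[-1]
print(m.psi_deg)          # ~75.7: the inclined torus rotates toward ~80 deg
```

The orientation angle rises from 45° toward a plateau near 80° while the
torus bends and elongates — the behaviour that makes inclined tori faster
(lower steady forcing) than horizontal ones.

## Command line

```sh
eulfsi run case.toml -o rundir     # run a TOML-configured case
eulfsi verify poiseuille           # print the verification error norms
eulfsi convergence --levels 16,32,64 --reference 128
eulfsi analyze rundir
```

Outputs: CSV time series (metric columns documented in
`eulfsi.shape.ShapeMetrics.COLUMNS`), VTK image-data snapshots (`.vti`),
STL isosurfaces, JSON summaries.

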