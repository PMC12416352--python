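# CSV series schemas

All series are comma-separated with a header row; missing metrics are empty
cells (never 0).  Times are dimensionless (t* = t U / D).

## Shape-metric series (`metrics.csv`, one row per snapshot)

| column | meaning |
| --- | --- |
| `time` | snapshot time t* |
| `xc_x, xc_y, xc_z` | volume-fraction-weighted particle centroid (domain coordinates, periodic axes wrapped into [0, L)) |
| `uc_x, uc_y, uc_z` | centroid velocity (alpha-weighted mean of the cell-centered velocity) |
| `psi_deg` | orientation angle: arccos of the orientation vector's x-component, degrees in [0, 90] |
| `aspect_forward, aspect_back` | min/max semi-axis ratio of the meridian-plane tube cross-sections (+eta / -eta loop) |
| `aspect_right, aspect_left` | same for the prime-vertical plane (+zeta / -zeta loop) |
| `bend_meridian_deg` | bending angle of the forward/back pair (0 = unbent; positive toward +xi) |
| `bend_prime_vertical_deg` | bending angle of the right/left pair |
| `projected_inner_ratio` | aspect ratio of the inner outline of the (zeta, eta) parallel projection; empty when the hole is not resolved |
| `projected_outer_ratio` | aspect ratio of the outer outline |

## Driver history (`series.csv` for pipe runs)

| column | meaning |
| --- | --- |
| `t` | time after the step |
| `dt` | step size used |
| `S` | accumulated uniform forcing (pressure-gradient readout; pressure drop = S x L) |
| `mean_u` | bulk axial velocity measured by the controller before its correction (NaN when no controller is active) |
| `solid_volume` | total solid volume (conservation monitor) |
| `div_residual` | max cell divergence after the projection |

## Cavity series

`t, xc_x, xc_y, uc_x, uc_y, solid_volume` — centroid trajectory and volume
monitor of the deformable disk.

## Stenosis series

| column | meaning |
| --- | --- |
| `t` | time since particle release |
| `pressure_drop` | pressure drop across the stenotic segment (cross-section means at x = L/4 and 3L/4) |
| `flow_rate` | outlet volumetric flow rate |
| `excess_pressure_drop` | `pressure_drop` minus the particle-free baseline at the same time (present when the run used a developed base flow) |
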