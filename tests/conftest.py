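import numpy as np
import pytest

from eulfsi.grid import CartesianGrid, VectorField


@pytest.fixture
def periodic_box_2d():
    return CartesianGrid((32, 32), (1.0, 1.0), periodic=(True, True))


@pytest.fixture
def closed_box_2d():
    return CartesianGrid((16, 16), (1.0, 1.0))


def shear_velocity(grid, gamma=1.0):
    """u = (gamma * y, 0) on the staggered grid."""
    u = VectorField(grid)
    yc = (np.arange(grid.shape3[1]) + 0.5) * grid.dx
    u.comps[0][:] = gamma * yc[None, :, None]
    u.sync_periodic()
    return u


def solenoidal_velocity(grid, seed=0):
    """Divergence-free staggered field from a random streamfunction."""
    rng = np.random.default_rng(seed)
    nx, ny = grid.shape3[0], grid.shape3[1]
    psi = rng.standard_normal((nx, ny))
    # smooth and scale so the face velocities are O(1)
    for _ in range(4):
        psi = 0.25 * (np.roll(psi, 1, 0) + np.roll(psi, -1, 0)
                      + np.roll(psi, 1, 1) + np.roll(psi, -1, 1))
    psi *= grid.dx / max(np.abs(np.diff(psi, axis=0)).max(),
                         np.abs(np.diff(psi, axis=1)).max(), 1e-30)
    u = VectorField(grid)
    dx = grid.dx
    # streamfunction at cell corners: discretely divergence-free by
    # construction on the periodic box
    u.comps[0][:-1, :, 0] = (np.roll(psi, -1, 1) - psi) / dx
    u.comps[1][:, :-1, 0] = -(np.roll(psi, -1, 0) - psi) / dx
    u.sync_periodic()
    return u
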