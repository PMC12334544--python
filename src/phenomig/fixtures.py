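"""Small deterministic lattice states and continuum fields for tests.

Every fixture is generated programmatically, reproducible from its seed,
and small enough (n_x, n_y <= 64) to keep test runs fast.
"""

from __future__ import annotations

import numpy as np

from .ibm import IBMState, LatticeConfig
from .pde import Fields, Grid

__all__ = ["make_lattice", "make_grid", "make_ibm_fixture", "make_field_fixture",
           "FIXTURE_KINDS"]

FIXTURE_KINDS = ("point_mass", "gaussian_bump", "step_front", "diagonal_line",
                 "uniform", "empty", "saturated")


def make_lattice(n_x: int = 20, n_y: int = 8, dt: float = 0.01,
                 site_capacity: int = 100, x_max: float = 10.0) -> LatticeConfig:
    return LatticeConfig(x_min=0.0, x_max=x_max, y_min=0.0, y_max=1.0,
                         n_x=n_x, n_y=n_y, dt=dt, site_capacity=site_capacity)


def make_grid(n_x: int = 20, n_y: int = 9, x_max: float = 10.0) -> Grid:
    return Grid(x_min=0.0, x_max=x_max, y_min=0.0, y_max=1.0, n_x=n_x, n_y=n_y)


def make_ibm_fixture(kind: str, lattice: LatticeConfig, seed: int = 0,
                     count: int = 50) -> IBMState:
    """Deterministic integer lattice states covering the preset IC shapes
    plus adversarial cases (empty, capacity-saturated)."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if lattice.n_x > 64 or lattice.n_y > 64:
        raise ValueError("fixtures are for small lattices (n_x, n_y <= 64)")
    rng = np.random.default_rng(seed)
    shape = lattice.shape
    n = np.zeros(shape, dtype=np.int64)
    e = np.zeros(shape[0], dtype=np.int64)
    if kind == "point_mass":
        n[shape[0] // 2, shape[1] // 2] = count
    elif kind == "gaussian_bump":
        X, Y = np.meshgrid(lattice.x, lattice.y, indexing="ij")
        prof = np.exp(-((X - lattice.x.mean()) ** 2 + (Y - 0.5) ** 2))
        n = rng.poisson(count * prof / prof.max() / shape[1])
    elif kind == "step_front":
        n[: shape[0] // 2, :] = max(1, count // shape[1])
        e[shape[0] // 2:] = lattice.site_capacity // 2
    elif kind == "diagonal_line":
        for j, yj in enumerate(lattice.y):
            i = int(np.argmin(np.abs(lattice.x - 5.0 * yj)))
            n[i, j] = count
    elif kind == "uniform":
        n[:, :] = max(1, count // shape[1])
    elif kind == "empty":
        pass
    elif kind == "saturated":
        n[:, :] = lattice.site_capacity // shape[1]
    return IBMState(n=n, e=e, t=0.0)


def make_field_fixture(kind: str, grid: Grid, seed: int = 0,
                       amplitude: float = 1.0) -> Fields:
    """Continuum counterparts of the lattice fixtures."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}")
    n = np.zeros(grid.shape)
    e = np.zeros(grid.n_x + 1)
    if kind == "point_mass":
        n[grid.n_x // 2, (grid.n_y + 1) // 2] = amplitude / grid.dy
    elif kind == "gaussian_bump":
        X, Y = np.meshgrid(grid.x, grid.y, indexing="ij")
        n = amplitude * np.exp(-((X - grid.x.mean()) ** 2 + (Y - 0.5) ** 2))
    elif kind == "step_front":
        n[: grid.n_x // 2, :] = amplitude
        e[grid.n_x // 2:] = amplitude / 2
    elif kind == "diagonal_line":
        for j, yj in enumerate(grid.y):
            i = int(np.argmin(np.abs(grid.x - 5.0 * yj)))
            n[i, j] = amplitude / grid.dy
    elif kind == "uniform":
        n[:, :] = amplitude
    elif kind == "saturated":
        n[:, :] = amplitude / (grid.dy * (grid.n_y + 1))
    return Fields(n=n, e=e, t=0.0)
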