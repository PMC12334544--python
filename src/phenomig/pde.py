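"""Method-of-lines solver for the phenotype-structured continuum model.

The cell density ``n(x, y, t)`` obeys

    dn/dt = d/dx( v_m n ) + d/dx( D_m dn/dx - n dD_m/dx )
          + d/dy( v_p n ) + d2/dy2( D_p n ) + r n,

with zero-flux boundary conditions on both axes, coupled to an environment
density ``e(x, t)`` with optional transport and growth.

Discretisation
--------------
* ``x``: node-centred flux-form central differences.  The flux
  ``G = v_m n + D_m dn/dx - n dD_m/dx`` is evaluated at cell interfaces
  (coefficients by arithmetic mean, gradients by central difference) and
  the boundary interface fluxes are set to exactly zero — the discrete
  form of the zero-flux conditions.  The scheme conserves ``sum_i n_i``
  exactly when ``r = 0``.
* ``y``: finite-volume cells with values at cell centres
  ``y_j = y_min + (j + 1/2) dy``, ``dy = (y_max - y_min)/(n_y + 1)``.
  The advective interface flux is reconstructed with the Koren
  (kappa = 1/3 MUSCL) limiter, upwinded on the interface velocity; the
  diffusive part is the second difference of the product ``w = D_p n``
  (the equation is written in Fokker–Planck form).  Boundary interface
  fluxes vanish identically.
* time: adaptive explicit Runge–Kutta of order 5(4) via
  ``scipy.integrate.solve_ivp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .coefficients import ContinuumCoefficients, EnvironmentDynamics

__all__ = [
    "Grid",
    "Fields",
    "SolverConfig",
    "Trajectory",
    "SolverError",
    "total_density",
    "spatial_rhs",
    "phenotype_rhs",
    "reaction_rhs",
    "environment_rhs",
    "solve",
]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class Grid:
    """Uniform grid: ``n_x + 1`` x-nodes, ``n_y + 1`` y-cells.

    The y-axis follows a cell-centred convention: ``n_y + 1`` cells of
    width ``dy = (y_max - y_min)/(n_y + 1)`` whose centres sit at
    ``y_min + (j + 1/2) dy``.  The midpoint quadrature
    ``rho = dy * sum_j n_j`` is then exact for linear integrands and is the
    quantity the finite-volume fluxes conserve.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    n_x: int
    n_y: int
    y_centers: np.ndarray | None = None  # override for lattice-aligned grids

    def __post_init__(self):
        if self.n_x < 4 or self.n_y < 0:
            raise ValueError("need n_x >= 4")
        if self.y_centers is not None:
            yc = np.asarray(self.y_centers, dtype=float)
            if yc.shape != (self.n_y + 1,):
                raise ValueError("y_centers must have n_y + 1 entries")
            object.__setattr__(self, "y_centers", yc)

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / self.n_x

    @property
    def dy(self) -> float:
        if self.y_centers is not None and self.n_y > 0:
            return float(self.y_centers[1] - self.y_centers[0])
        return (self.y_max - self.y_min) / (self.n_y + 1)

    @property
    def x(self) -> np.ndarray:
        return self.x_min + self.dx * np.arange(self.n_x + 1)

    @property
    def y(self) -> np.ndarray:
        if self.y_centers is not None:
            return self.y_centers
        return self.y_min + self.dy * (np.arange(self.n_y + 1) + 0.5)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_x + 1, self.n_y + 1)

    @staticmethod
    def lattice_aligned(lattice) -> "Grid":
        """Grid whose y-cells sit exactly on an IBM lattice's phenotype states."""
        return Grid(
            x_min=lattice.x_min, x_max=lattice.x_max,
            y_min=lattice.y_min, y_max=lattice.y_max,
            n_x=lattice.n_x, n_y=lattice.n_y,
            y_centers=lattice.y.copy(),
        )


@dataclass(frozen=True)
class Fields:
    """Continuum densities on the grid at time ``t``."""

    n: np.ndarray  # (n_x+1, n_y+1)
    e: np.ndarray  # (n_x+1,)
    t: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "n", np.asarray(self.n, dtype=float))
        object.__setattr__(self, "e", np.asarray(self.e, dtype=float))
        if self.n.ndim != 2 or self.e.shape != (self.n.shape[0],):
            raise ValueError("n must be 2-d and e match its first axis")
        if not (np.isfinite(self.n).all() and np.isfinite(self.e).all()):
            raise ValueError("fields must be finite")


@dataclass(frozen=True)
class SolverConfig:
    rtol: float = 1e-6
    atol: float = 1e-9
    max_step: float = 0.1
    save_times: np.ndarray | None = None
    limiter: str = "koren"  # koren | upwind | none
    tol_neg: float = 1e-8

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")
        if self.limiter not in ("koren", "upwind", "none"):
            raise ValueError(f"unknown limiter {self.limiter!r}")
        if self.save_times is not None:
            st = np.asarray(self.save_times, dtype=float)
            if st.ndim != 1 or len(st) < 2 or (np.diff(st) <= 0).any():
                raise ValueError("save_times must be strictly increasing, length >= 2")
            object.__setattr__(self, "save_times", st)


@dataclass(frozen=True)
class Trajectory:
    """Saved continuum fields, with integrator statistics."""

    times: np.ndarray
    fields: list[Fields]
    n_rhs_evaluations: int = 0
    n_steps: int = 0

    def __len__(self) -> int:
        return len(self.fields)

    @property
    def final(self) -> Fields:
        return self.fields[-1]


def total_density(n: np.ndarray, grid: Grid) -> np.ndarray:
    """``rho(x) = ∫ n dy`` by the midpoint rule over y-cells."""
    n = np.asarray(n)
    if n.shape[-1] != grid.n_y + 1:
        raise ValueError("n does not match the grid's y-cells")
    return n.sum(axis=-1) * grid.dy


def spatial_rhs(
    n: np.ndarray, e: np.ndarray, coeffs: ContinuumCoefficients, grid: Grid
) -> np.ndarray:
    """x-transport: ``d/dx( v_m n + D_m dn/dx - n dD_m/dx )``."""
    dx = grid.dx
    y = grid.y[None, :]
    rho = total_density(n, grid)[:, None]
    Dm = np.broadcast_to(coeffs.D_m(y, rho, e[:, None]), n.shape)
    vm = np.broadcast_to(coeffs.v_m(y, rho, e[:, None]), n.shape)
    if not (np.isfinite(Dm).all() and np.isfinite(vm).all()):
        raise SolverError("non-finite spatial coefficient evaluation")
    nbar = 0.5 * (n[1:] + n[:-1])
    Dbar = 0.5 * (Dm[1:] + Dm[:-1])
    vbar = 0.5 * (vm[1:] + vm[:-1])
    G = vbar * nbar + Dbar * (n[1:] - n[:-1]) / dx - nbar * (Dm[1:] - Dm[:-1]) / dx
    out = np.zeros_like(n)
    out[:-1] += G / dx
    out[1:] -= G / dx
    return out


def _koren_phi(theta: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, np.minimum(np.minimum(2.0 * theta, (1.0 + 2.0 * theta) / 3.0), 2.0))


def _limited_face_values(n: np.ndarray, limiter: str) -> tuple[np.ndarray, np.ndarray]:
    """Reconstructed values on interior y-interfaces from the left and right.

    Returns (from_below, from_above), each of shape (..., n_cells - 1),
    for interface j+1/2 between cells j and j+1.  Ghost cells replicate the
    edge value (zero-gradient), which the zero boundary flux makes immaterial.
    """
    pad = np.concatenate([n[..., :1], n, n[..., -1:]], axis=-1)
    d = np.diff(pad, axis=-1)              # d[..., k] = n_k - n_{k-1} (ghost-padded)
    up = d[..., :-1]                       # slope behind cell j   (j = 0..Nc-1)
    dn = d[..., 1:]                        # slope ahead of cell j
    if limiter == "none":
        centered = n[..., :-1] + 0.5 * np.diff(n, axis=-1)
        return centered, centered
    if limiter == "upwind":
        return n[..., :-1], n[..., 1:]
    def _safe_ratio(num, den):
        # sign-preserving floor on the denominator keeps theta finite
        den_safe = np.where(den >= 0.0, np.maximum(den, 1e-100),
                            np.minimum(den, -1e-100))
        return num / den_safe

    theta_lo = _safe_ratio(dn[..., :-1], up[..., :-1])
    lo = n[..., :-1] + 0.5 * _koren_phi(theta_lo) * up[..., :-1]
    theta_hi = _safe_ratio(up[..., 1:], dn[..., 1:])
    hi = n[..., 1:] - 0.5 * _koren_phi(theta_hi) * dn[..., 1:]
    return lo, hi


def phenotype_rhs(
    n: np.ndarray,
    e: np.ndarray,
    coeffs: ContinuumCoefficients,
    grid: Grid,
    limiter: str = "koren",
) -> np.ndarray:
    """y-transport: ``d/dy( v_p n ) + d2/dy2( D_p n )`` in flux form.

    The transport velocity for the conservative flux is ``u = -v_p``
    (positive ``v_p`` moves mass toward smaller ``y``).  Interface fluxes at
    ``y_min`` and ``y_max`` are exactly zero.
    """
    dy = grid.dy
    ncells = grid.n_y + 1
    if ncells < 2:
        return np.zeros_like(n)
    y = grid.y[None, :]
    rho = total_density(n, grid)[:, None]
    Dp = np.broadcast_to(coeffs.D_p(y, rho, e[:, None]), n.shape)
    if not np.isfinite(Dp).all():
        raise SolverError("non-finite phenotype coefficient evaluation")

    # interface velocities at y_{j+1/2}
    y_half = 0.5 * (grid.y[:-1] + grid.y[1:])[None, :]
    vp_half = np.broadcast_to(coeffs.v_p(y_half, rho, e[:, None]),
                              n.shape[:-1] + (ncells - 1,))
    u = -vp_half

    if np.any(vp_half) or limiter == "none":
        lo, hi = _limited_face_values(n, limiter)
        n_face = np.where(u > 0, lo, np.where(u < 0, hi, 0.5 * (lo + hi)))
        F_adv = u * n_face
    else:
        F_adv = 0.0

    w = Dp * n
    F_dif = -(w[..., 1:] - w[..., :-1]) / dy
    F = F_adv + F_dif
    out = np.zeros_like(n)
    out[..., :-1] -= F / dy
    out[..., 1:] += F / dy
    return out


def reaction_rhs(
    n: np.ndarray, e: np.ndarray, coeffs: ContinuumCoefficients, grid: Grid
) -> np.ndarray:
    """Net growth ``r(y, rho, e) * n``."""
    y = grid.y[None, :]
    rho = total_density(n, grid)[:, None]
    r = coeffs.r(y, rho, e[:, None])
    if not np.isfinite(np.asarray(r)).all():
        raise SolverError("non-finite growth-rate evaluation")
    return r * n


def environment_rhs(
    n: np.ndarray,
    e: np.ndarray,
    coeffs: ContinuumCoefficients,
    env: EnvironmentDynamics,
    grid: Grid,
) -> np.ndarray:
    """``de/dt = -(∫ nu dy) e + g e + d/dx( D_e de/dx - e dD_e/dx )``."""
    y = grid.y[None, :]
    loss = (coeffs.nu(y, n) * np.ones_like(n)).sum(axis=-1) * grid.dy
    rho = total_density(n, grid)
    out = -loss * e + env.g(rho, e) * e

    De = np.broadcast_to(np.asarray(env.D_e(rho, e), dtype=float), e.shape)
    if De.any():
        dx = grid.dx
        ebar = 0.5 * (e[1:] + e[:-1])
        Dbar = 0.5 * (De[1:] + De[:-1])
        G = Dbar * (e[1:] - e[:-1]) / dx - ebar * (De[1:] - De[:-1]) / dx
        out = out.copy()
        out[:-1] += G / dx
        out[1:] -= G / dx
    return out


def solve(
    fields0: Fields,
    coeffs: ContinuumCoefficients,
    env: EnvironmentDynamics,
    grid: Grid,
    config: SolverConfig,
) -> Trajectory:
    """Integrate the coupled system and return fields at the save times."""
    if fields0.n.shape != grid.shape:
        raise ValueError("initial fields do not match the grid")
    if config.save_times is None:
        raise ValueError("SolverConfig.save_times is required")
    save_times = config.save_times
    shape = grid.shape
    nn = shape[0] * shape[1]
    blow_up = 10.0 / grid.dy * max(1.0, np.abs(fields0.n).max() * grid.dy)

    def rhs(t, u):
        n = u[:nn].reshape(shape)
        e = u[nn:]
        dn = spatial_rhs(n, e, coeffs, grid)
        dn += phenotype_rhs(n, e, coeffs, grid, config.limiter)
        dn += reaction_rhs(n, e, coeffs, grid)
        de = environment_rhs(n, e, coeffs, env, grid)
        return np.concatenate([dn.ravel(), de])

    u0 = np.concatenate([fields0.n.ravel(), fields0.e])
    sol = solve_ivp(
        rhs,
        (save_times[0], save_times[-1]),
        u0,
        method="RK45",
        t_eval=save_times,
        rtol=config.rtol,
        atol=config.atol,
        max_step=config.max_step,
    )
    if not sol.success:
        raise SolverError(f"integration failed: {sol.message}")
    fields = []
    for k, t in enumerate(sol.t):
        n = sol.y[:nn, k].reshape(shape)
        e = sol.y[nn:, k]
        if np.abs(n).max() > blow_up:
            raise SolverError(f"solution blow-up detected at t = {t:.4g}")
        fields.append(Fields(n=n, e=e, t=float(t)))
    return Trajectory(
        times=sol.t.copy(), fields=fields,
        n_rhs_evaluations=int(sol.nfev), n_steps=len(sol.t),
    )
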