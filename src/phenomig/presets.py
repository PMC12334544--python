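"""The three packaged applications of the framework.

* ``range_expansion`` — phenotype as a passive lineage label during a
  pulled (Fisher-KPP, ``r = 1 - rho``) or pushed (Allee,
  ``r = (1 - rho)(rho - p*)``) invasion.  No phenotype transport and no
  environment: the total density obeys the classical scalar equation, while
  the structured density records which lineages surf the front.
* ``go_or_grow`` — the migration–proliferation dichotomy during invasion of
  the extracellular matrix (ECM).  Low phenotypes move and degrade ECM but
  do not divide; high phenotypes divide but do not move.  Three variants of
  the phenotypic drift (cell-, ECM- and space-dependent) are provided.
* ``t_cell`` — T cells infiltrating a tumour, with the phenotype read as
  inverse exhaustion (``y = 1`` naive, ``y = 0`` exhausted).  The tumour is
  the environment field, itself motile and proliferating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coefficients import ContinuumCoefficients, EnvironmentDynamics, zero
from .pde import Fields, Grid

__all__ = ["Preset", "PresetParameters", "range_expansion", "go_or_grow", "t_cell",
           "preset_by_name"]


@dataclass(frozen=True)
class PresetParameters:
    """Tunable model parameters with the defaults used throughout.

    kappa      carrying capacity (density units); all presets use 1.
    p_star     Allee threshold, in (0, 1/2).
    gamma0     T-cell death rate of fully exhausted cells.
    gamma1     T-cell maximal growth rate of naive cells.
    k1, k2     exhaustion rates from activity and from tumour contact.
    epsilon    small phenotypic diffusivity of the T cells.
    r_C        tumour growth rate.
    lambda_bar T-cell toxicity on the tumour.
    """

    kappa: float = 1.0
    p_star: float = 0.25
    gamma0: float = 1.0
    gamma1: float = 10.0
    k1: float = 0.5
    k2: float = 0.5
    epsilon: float = 0.01
    r_C: float = 0.1
    lambda_bar: float = 10.0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not (0.0 < self.p_star < 0.5):
            raise ValueError("p_star must lie in (0, 1/2)")
        for name in ("gamma0", "gamma1", "k1", "k2", "r_C", "lambda_bar"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class Preset:
    """A model instance: coefficients, environment dynamics and initial data."""

    name: str
    coeffs: ContinuumCoefficients
    env: EnvironmentDynamics
    params: PresetParameters

    def initial_fields(self, grid: Grid) -> Fields:
        return self._ic(grid)

    _ic: callable = field(repr=False, default=None)


def _diagonal_line_ic(grid: Grid) -> Fields:
    """Initial lineage labelling along the line x = 5 y.

    For each phenotype cell j, density 1/dy is deposited in the x-node
    nearest ``5 y_j``, so the deposited total density along the occupied
    diagonal is O(1) and the initial mass is independent of dy.
    """
    n = np.zeros(grid.shape)
    x = grid.x
    for j, yj in enumerate(grid.y):
        i = int(np.argmin(np.abs(x - 5.0 * yj)))
        n[i, j] += 1.0 / grid.dy
    return Fields(n=n, e=np.zeros(grid.n_x + 1), t=0.0)


def range_expansion(growth: str = "fisher", p_star: float = 0.25,
                    params: PresetParameters | None = None) -> Preset:
    """Range expansion with a phenotypically labelled but homogeneous population.

    ``growth`` selects the net proliferation law: ``"fisher"`` gives the
    logistic ``r = 1 - rho`` (pulled front, asymptotic speed ``2 sqrt(r D) = 2``),
    ``"allee"`` the bistable ``r = (1 - rho)(rho - p*)`` (pushed front, exact
    speed ``(1 - 2 p*) / sqrt(2)`` for the cubic nonlinearity).
    """
    if growth not in ("fisher", "allee"):
        raise ValueError(f"unknown growth law {growth!r}")
    params = params or PresetParameters(p_star=p_star)
    if growth == "allee":
        p = params.p_star

        def r(y, rho, e):
            return (1.0 - rho) * (rho - p) * np.ones_like(y)
    else:
        def r(y, rho, e):
            return (1.0 - rho) * np.ones_like(y)

    coeffs = ContinuumCoefficients(
        D_m=lambda y, rho, e: np.ones(np.broadcast(y, rho, e).shape),
        r=r,
    )
    return Preset(name=f"range_expansion_{growth}", coeffs=coeffs,
                  env=EnvironmentDynamics.static(), params=params,
                  _ic=_diagonal_line_ic)


def _bump_ic(grid: Grid, y_center: float, kappa: float) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian bump exp(-100(x^2 + (y - y_center)^2)), normalised so the
    initial total density peaks at the carrying capacity, plus the
    complementary environment profile (0 under the bump, kappa/2 outside).

    The normaliser max_y ∫ exp(-100(x^2 + (y - y_center)^2)) dx is evaluated
    analytically (the bump is far narrower than a grid cell would resolve
    accurately by discrete quadrature); if the midpoint quadrature of the
    resulting total density still overshoots kappa, the bump is rescaled so
    the volume-filling coefficients stay in their admissible range.
    """
    from scipy.special import erf

    X, Y = np.meshgrid(grid.x, grid.y, indexing="ij")
    raw = np.exp(-100.0 * (X**2 + (Y - y_center) ** 2))
    # ∫ exp(-100 x^2) dx over the domain, at the maximising phenotype
    Z = np.sqrt(np.pi) / 20.0 * 0.5 * (erf(10.0 * grid.x_max) - erf(10.0 * grid.x_min))
    n0 = kappa * raw / Z
    rho_max = (n0.sum(axis=1) * grid.dy).max()
    if rho_max > kappa:
        n0 *= kappa / rho_max
    occupied = raw.max(axis=1) > 0.001
    e0 = np.where(occupied, 0.0, 0.5 * kappa)
    return n0, e0


def go_or_grow(drift_variant: str = "cell",
               params: PresetParameters | None = None) -> Preset:
    """Go-or-grow invasion of the ECM with a continuum of phenotypes.

    Coefficients (volume-filling, kappa the shared carrying capacity):

        D_m = (1 - y)(1 - (rho + e)/kappa)      motile low phenotypes
        r   = y (1 - (rho + e)/kappa)           proliferative high phenotypes
        nu  = (1 - y) n                         degradation by motile cells
        D_p = 1

    The phenotypic drift depends on the chosen variant:
    ``cell``: v_p = 2 rho/kappa - 1;  ``ecm``: v_p = 2 e/kappa - 1;
    ``space``: v_p = 2 (rho + e)/kappa - 1.  Positive v_p pushes cells
    toward low (motile) phenotypes.
    """
    if drift_variant not in ("cell", "ecm", "space"):
        raise ValueError(f"unknown drift variant {drift_variant!r}")
    params = params or PresetParameters()
    kappa = params.kappa

    def D_m(y, rho, e):
        return (1.0 - y) * (1.0 - (rho + e) / kappa)

    def r(y, rho, e):
        return y * (1.0 - (rho + e) / kappa)

    def nu(y, n):
        return (1.0 - y) * n

    if drift_variant == "cell":
        v_p = lambda y, rho, e: (2.0 * rho / kappa - 1.0) * np.ones_like(y)
    elif drift_variant == "ecm":
        v_p = lambda y, rho, e: (2.0 * e / kappa - 1.0) * np.ones_like(y)
    else:
        v_p = lambda y, rho, e: (2.0 * (rho + e) / kappa - 1.0) * np.ones_like(y)

    coeffs = ContinuumCoefficients(
        D_m=D_m, v_p=v_p,
        D_p=lambda y, rho, e: np.ones(np.broadcast(y, rho, e).shape),
        r=r, nu=nu,
    )

    def ic(grid: Grid) -> Fields:
        n0, e0 = _bump_ic(grid, y_center=0.0, kappa=kappa)
        return Fields(n=n0, e=e0, t=0.0)

    return Preset(name=f"go_or_grow_{drift_variant}", coeffs=coeffs,
                  env=EnvironmentDynamics.static(), params=params, _ic=ic)


def t_cell(params: PresetParameters | None = None) -> Preset:
    """T cells invading a motile, proliferating tumour.

    The structured density is the T-cell population; the environment field
    is the tumour density C(x, t).  With y the (inverse) exhaustion level:

        r   = gamma1 y (1 - (rho + C)/kappa) - gamma0 (1 - y)
        D_m = y (1 - (rho + C)/kappa)
        v_p = y (k1 + k2 C)          exhaustion from activity and contact
        D_p = epsilon
        nu  = lambda_bar y n         T-cell toxicity on the tumour
        D_C = 1 - (rho + C)/kappa,  g = r_C (1 - (rho + C)/kappa)
    """
    params = params or PresetParameters()
    kappa, g0, g1 = params.kappa, params.gamma0, params.gamma1
    k1, k2, eps = params.k1, params.k2, params.epsilon
    r_C, lam_bar = params.r_C, params.lambda_bar

    coeffs = ContinuumCoefficients(
        D_m=lambda y, rho, e: y * (1.0 - (rho + e) / kappa),
        v_p=lambda y, rho, e: y * (k1 + k2 * e),
        D_p=lambda y, rho, e: eps * np.ones(np.broadcast(y, rho, e).shape),
        r=lambda y, rho, e: g1 * y * (1.0 - (rho + e) / kappa) - g0 * (1.0 - y),
        nu=lambda y, n: lam_bar * y * n,
    )
    env = EnvironmentDynamics(
        D_e=lambda rho, e: 1.0 - (rho + e) / kappa,
        g=lambda rho, e: r_C * (1.0 - (rho + e) / kappa),
    )

    def ic(grid: Grid) -> Fields:
        n0, e0 = _bump_ic(grid, y_center=1.0, kappa=kappa)
        return Fields(n=n0, e=e0, t=0.0)

    return Preset(name="t_cell", coeffs=coeffs, env=env, params=params, _ic=ic)


def preset_by_name(name: str, **kwargs) -> Preset:
    """Look up a preset constructor by its config-file name."""
    table = {
        "range_expansion": range_expansion,
        "go_or_grow": go_or_grow,
        "t_cell": t_cell,
    }
    if name not in table:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(table)}")
    return table[name](**kwargs)
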