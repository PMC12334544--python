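"""Coefficient functions of the coarse-grained transport model.

The continuum limit of the lattice model is a reaction–advection–diffusion
equation for the phenotype-structured cell density ``n(x, y, t)``,

    dn/dt = d/dx( v_m n ) + d/dx( D_m dn/dx - n dD_m/dx )
          + d/dy( v_p n ) + d2/dy2( D_p n ) + r n,

coupled to a spatially structured environment density ``e(x, t)``,

    de/dt = -( ∫ nu(y, n) dy ) e + g(rho, e) e
          + d/dx( D_e de/dx - e dD_e/dx ).

All coefficients may depend on the phenotype ``y``, the total cell density
``rho(x, t) = ∫ n dy`` and the local environment density ``e(x, t)``; the
environment-loss kernel ``nu`` depends on ``y`` and on the structured
density ``n(x, y, t)`` itself.

Every callable must be vectorised (accept numpy arrays and broadcast).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["ContinuumCoefficients", "EnvironmentDynamics", "zero"]


def zero(*args):
    """Coefficient that is identically zero for any broadcast arguments."""
    return np.zeros(np.broadcast(*args).shape) if args else 0.0


# signatures: f(y, rho, e) except nu(y, n)
CoefFn = Callable[..., np.ndarray]


@dataclass(frozen=True)
class ContinuumCoefficients:
    """The six coefficient functions of the cell equation.

    Parameters
    ----------
    v_m, D_m : callable(y, rho, e)
        Spatial drift and diffusivity. Positive ``v_m`` transports mass
        toward smaller ``x`` (the drift enters as ``+d/dx(v_m n)``).
    v_p, D_p : callable(y, rho, e)
        Phenotypic drift and diffusivity. Positive ``v_p`` transports mass
        toward smaller ``y``.
    r : callable(y, rho, e)
        Net per-capita growth rate (may be negative).
    nu : callable(y, n)
        Environment-loss kernel; the environment decays at rate
        ``∫ nu(y, n(x, y, t)) dy``.
    """

    v_m: CoefFn = zero
    D_m: CoefFn = zero
    v_p: CoefFn = zero
    D_p: CoefFn = zero
    r: CoefFn = zero
    nu: CoefFn = zero


@dataclass(frozen=True)
class EnvironmentDynamics:
    """Transport and growth of the environment field.

    A static, purely degraded environment (extracellular matrix) has
    ``D_e = g = 0``; a motile, proliferating environment (a tumour-cell
    population) supplies both.
    """

    D_e: CoefFn = zero  # D_e(rho, e)
    g: CoefFn = zero    # g(rho, e), per-capita growth

    @property
    def is_static(self) -> bool:
        return self.D_e is zero and self.g is zero

    @staticmethod
    def static() -> "EnvironmentDynamics":
        return EnvironmentDynamics()
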