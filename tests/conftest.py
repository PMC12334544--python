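import numpy as np
import pytest

import phenomig as pm
from phenomig.coefficients import ContinuumCoefficients, EnvironmentDynamics


@pytest.fixture
def small_lattice():
    return pm.LatticeConfig(x_min=0.0, x_max=10.0, y_min=0.0, y_max=1.0,
                            n_x=20, n_y=8, dt=0.01, site_capacity=100)


@pytest.fixture
def small_grid():
    return pm.Grid(x_min=0.0, x_max=10.0, y_min=0.0, y_max=1.0, n_x=20, n_y=9)


def const_rule(value):
    """A transition rule that ignores its arguments."""
    def rule(j, N, e):
        return np.full(np.broadcast(j, N, e).shape, float(value))
    return rule


def diffusion_coeffs(D=1.0, growth=None):
    """Spatial diffusion plus an optional growth law r(rho)."""
    kw = {"D_m": lambda y, rho, e: D * np.ones(np.broadcast(y, rho, e).shape)}
    if growth is not None:
        kw["r"] = lambda y, rho, e: growth(rho) * np.ones_like(y)
    return ContinuumCoefficients(**kw)


@pytest.fixture
def static_env():
    return EnvironmentDynamics.static()
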