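"""Stochastic on-lattice individual-based model (IBM) of cell migration.

Cells live on a regular (space x phenotype) lattice with sites
``x_i = x_min + i*dx`` (``i = 0..n_x``) and phenotype states
``y_j = y_min + j*dy`` (``j = 0..n_y``).  The state records the integer
occupancy ``n[i, j]`` together with an integer count ``e[i]`` of discrete
environment elements per spatial site.

In one time step of length ``dt`` every cell performs at most one event:
move left/right (probabilities evaluated at the *target* site's total cell
and environment counts), switch phenotype down/up (evaluated at the
*current* site), divide in place, or die.  Independently, every environment
element at site ``i`` is removed with probability
``min(1, sum_j lam(j, n[i, j]))``.  All probabilities are evaluated on the
start-of-step state and the resulting changes are applied simultaneously
(synchronous update), matching the one-event-per-step bookkeeping of the
mean-field derivation.

Cells can never leave the lattice: moves out of ``i = 0`` / ``i = n_x`` and
phenotype switches out of ``j = 0`` / ``j = n_y`` are forced to probability
zero by the engine, whatever the supplied rule functions return.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .coefficients import ContinuumCoefficients

__all__ = [
    "LatticeConfig",
    "IBMState",
    "TransitionRules",
    "IBMTrajectory",
    "EnsembleResult",
    "InvalidRulesError",
    "InvalidScalingError",
    "step",
    "simulate",
    "ensemble_mean",
    "rules_from_coefficients",
]


class InvalidRulesError(ValueError):
    """Event probabilities at some lattice cell are not a valid partition."""


class InvalidScalingError(ValueError):
    """A coefficient inversion produced an out-of-range probability."""


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry and time step of the lattice.

    ``site_capacity`` (``K``) is the cell+environment count at which a site
    is considered full; it converts integer counts to density fractions via
    ``rho = kappa * N / K``.  Larger ``K`` means lower demographic noise.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    n_x: int
    n_y: int
    dt: float
    site_capacity: int = 100

    def __post_init__(self):
        if self.n_x < 1 or self.n_y < 0:
            raise ValueError("need n_x >= 1 and n_y >= 0")
        if self.x_max <= self.x_min:
            raise ValueError("x_max must exceed x_min")
        if self.n_y > 0 and self.y_max <= self.y_min:
            raise ValueError("y_max must exceed y_min when n_y > 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.site_capacity < 1:
            raise ValueError("site_capacity must be >= 1")

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / self.n_x

    @property
    def dy(self) -> float:
        if self.n_y == 0:
            return self.y_max - self.y_min if self.y_max > self.y_min else 1.0
        return (self.y_max - self.y_min) / self.n_y

    @property
    def x(self) -> np.ndarray:
        return self.x_min + self.dx * np.arange(self.n_x + 1)

    @property
    def y(self) -> np.ndarray:
        return self.y_min + self.dy * np.arange(self.n_y + 1)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_x + 1, self.n_y + 1)


@dataclass(frozen=True)
class IBMState:
    """Integer occupancies on the lattice at time ``t``."""

    n: np.ndarray  # (n_x+1, n_y+1) int64
    e: np.ndarray  # (n_x+1,) int64
    t: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "n", np.asarray(self.n, dtype=np.int64))
        object.__setattr__(self, "e", np.asarray(self.e, dtype=np.int64))
        if self.n.ndim != 2 or self.e.ndim != 1 or self.e.shape[0] != self.n.shape[0]:
            raise ValueError("n must be (sites, states) and e (sites,)")
        if (self.n < 0).any() or (self.e < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total_per_site(self) -> np.ndarray:
        """``N_i = sum_j n[i, j]`` (always recomputed)."""
        return self.n.sum(axis=1)

    def validate_on(self, lattice: LatticeConfig) -> None:
        if self.n.shape != lattice.shape:
            raise ValueError(
                f"state shape {self.n.shape} does not match lattice {lattice.shape}"
            )


# Each rule is called with broadcastable arrays:
#   beta/mu/gamma/death: f(j, N, e) -> probability
#   lam: f(j, n_ij) -> per-element degradation probability contribution
RuleFn = Callable[..., np.ndarray]


def _zero_rule(*args):
    return np.zeros(np.broadcast(*args).shape)


@dataclass(frozen=True)
class TransitionRules:
    """The per-step event probabilities.

    ``beta_minus``/``beta_plus`` are evaluated at the *target* site's
    ``(N, e)``; ``mu_minus``/``mu_plus``, ``gamma`` and ``death`` at the
    current site's.  ``death`` extends the framework to negative net growth
    (the continuum ``r`` may be negative); for a pure-birth model leave it
    at zero.
    """

    beta_minus: RuleFn = _zero_rule
    beta_plus: RuleFn = _zero_rule
    mu_minus: RuleFn = _zero_rule
    mu_plus: RuleFn = _zero_rule
    gamma: RuleFn = _zero_rule
    death: RuleFn = _zero_rule
    lam: RuleFn = _zero_rule


@dataclass(frozen=True)
class IBMTrajectory:
    times: np.ndarray
    states: list[IBMState]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class EnsembleResult:
    """Ensemble means and standard errors over replicate simulations."""

    times: np.ndarray
    mean_n: np.ndarray  # (T, n_x+1, n_y+1)
    se_n: np.ndarray
    mean_e: np.ndarray  # (T, n_x+1)
    se_e: np.ndarray
    n_reps: int
    seed: int


def _event_probabilities(
    state: IBMState, rules: TransitionRules, lattice: LatticeConfig
) -> np.ndarray:
    """Per-cell event probabilities on the start-of-step state.

    Returns an array of shape (n_x+1, n_y+1, 6) ordered
    (left, right, down, up, divide, die).
    """
    nx1, ny1 = lattice.shape
    N = state.total_per_site.astype(float)
    e = state.e.astype(float)
    J = np.arange(ny1)[None, :]

    p = np.zeros((nx1, ny1, 6))
    # movement: evaluated at the target site, zero at the domain ends
    p[1:, :, 0] = np.broadcast_to(rules.beta_minus(J, N[:-1, None], e[:-1, None]),
                                  (nx1 - 1, ny1))
    p[:-1, :, 1] = np.broadcast_to(rules.beta_plus(J, N[1:, None], e[1:, None]),
                                   (nx1 - 1, ny1))
    # phenotype switches, proliferation, death: evaluated at the current site
    Nc, ec = N[:, None], e[:, None]
    p[:, 1:, 2] = np.broadcast_to(rules.mu_minus(J, Nc, ec), (nx1, ny1))[:, 1:]
    p[:, :-1, 3] = np.broadcast_to(rules.mu_plus(J, Nc, ec), (nx1, ny1))[:, :-1]
    p[:, :, 4] = np.broadcast_to(rules.gamma(J, Nc, ec), (nx1, ny1))
    p[:, :, 5] = np.broadcast_to(rules.death(J, Nc, ec), (nx1, ny1))
    return p


def _check_probabilities(p: np.ndarray, occupied: np.ndarray) -> None:
    tol = 1e-12
    if (p < -tol).any():
        i, j, k = np.unravel_index(np.argmin(p), p.shape)
        raise InvalidRulesError(
            f"negative event probability {p[i, j, k]:.3g} at site i={i}, state j={j}"
        )
    total = p.sum(axis=2)
    bad = occupied & (total > 1.0 + tol)
    if bad.any():
        masked = np.where(bad, total, -np.inf)
        i, j = np.unravel_index(np.argmax(masked), total.shape)
        raise InvalidRulesError(
            f"event probabilities sum to {total[i, j]:.6g} > 1 "
            f"at site i={i}, state j={j}; reduce dt"
        )


def step(
    state: IBMState,
    rules: TransitionRules,
    lattice: LatticeConfig,
    rng: np.random.Generator,
) -> IBMState:
    """Advance the lattice one synchronous time step."""
    state.validate_on(lattice)
    p = _event_probabilities(state, rules, lattice)
    occupied = state.n > 0
    _check_probabilities(p, occupied)

    # one uniform draw per cell <=> multinomial partition of the site count
    pvals = np.concatenate(
        [p, np.clip(1.0 - p.sum(axis=2), 0.0, 1.0)[..., None]], axis=2
    )
    pvals /= pvals.sum(axis=2, keepdims=True)
    counts = rng.multinomial(state.n, pvals)  # (nx1, ny1, 7)
    left, right, down, up, divide, die = (counts[..., k] for k in range(6))

    new_n = state.n - left - right - down - up - die + divide
    new_n[:-1, :] += left[1:, :]
    new_n[1:, :] += right[:-1, :]
    new_n[:, :-1] += down[:, 1:]
    new_n[:, 1:] += up[:, :-1]
    if (new_n < 0).any():
        raise RuntimeError("internal consistency error: negative occupancy")

    # environment degradation: one Bernoulli trial per element
    J = np.arange(lattice.n_y + 1)[None, :]
    lam = np.broadcast_to(rules.lam(J, state.n.astype(float)), state.n.shape)
    p_deg = np.minimum(1.0, np.maximum(0.0, lam.sum(axis=1)))
    removed = rng.binomial(state.e, p_deg)
    new_e = state.e - removed

    return IBMState(n=new_n, e=new_e, t=state.t + lattice.dt)


def simulate(
    state0: IBMState,
    rules: TransitionRules,
    lattice: LatticeConfig,
    n_steps: int,
    save_every: int = 1,
    seed: int = 0,
) -> IBMTrajectory:
    """Run ``n_steps`` steps, saving every ``save_every``-th state.

    A deterministic function of ``(state0, rules, lattice, n_steps, seed)``.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if save_every < 1:
        raise ValueError("save_every must be >= 1")
    rng = np.random.default_rng(seed)
    states = [state0]
    times = [state0.t]
    state = state0
    for h in range(1, n_steps + 1):
        try:
            state = step(state, rules, lattice, rng)
        except InvalidRulesError as err:
            raise InvalidRulesError(f"at step {h}: {err}") from err
        if h % save_every == 0 or h == n_steps:
            states.append(state)
            times.append(state.t)
    return IBMTrajectory(times=np.asarray(times), states=states, seed=seed)


def ensemble_mean(
    state0: IBMState,
    rules: TransitionRules,
    lattice: LatticeConfig,
    n_steps: int,
    n_reps: int,
    seed: int = 0,
    save_every: int = 1,
) -> EnsembleResult:
    """Arithmetic mean over independent replicates, with standard errors.

    Replicate generators are spawned from a single ``SeedSequence(seed)``,
    so the ensemble is reproducible and each replicate stream independent.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_reps)

    sum_n = sum_n2 = sum_e = sum_e2 = times = None
    for child in children:
        rng = np.random.default_rng(child)
        states = [state0]
        state = state0
        saved = [state0]
        for h in range(1, n_steps + 1):
            state = step(state, rules, lattice, rng)
            if h % save_every == 0 or h == n_steps:
                saved.append(state)
        ns = np.stack([s.n for s in saved]).astype(float)
        es = np.stack([s.e for s in saved]).astype(float)
        if sum_n is None:
            times = np.asarray([s.t for s in saved])
            sum_n, sum_n2 = ns.copy(), ns**2
            sum_e, sum_e2 = es.copy(), es**2
        else:
            sum_n += ns
            sum_n2 += ns**2
            sum_e += es
            sum_e2 += es**2

    mean_n = sum_n / n_reps
    mean_e = sum_e / n_reps
    if n_reps > 1:
        var_n = np.maximum(sum_n2 / n_reps - mean_n**2, 0.0) * n_reps / (n_reps - 1)
        var_e = np.maximum(sum_e2 / n_reps - mean_e**2, 0.0) * n_reps / (n_reps - 1)
        se_n = np.sqrt(var_n / n_reps)
        se_e = np.sqrt(var_e / n_reps)
    else:
        se_n = np.zeros_like(mean_n)
        se_e = np.zeros_like(mean_e)
    return EnsembleResult(
        times=times, mean_n=mean_n, se_n=se_n, mean_e=mean_e, se_e=se_e,
        n_reps=n_reps, seed=seed,
    )


def rules_from_coefficients(
    coeffs: ContinuumCoefficients,
    lattice: LatticeConfig,
    kappa: float = 1.0,
    validate_samples: int = 200,
    validate_seed: int = 0,
) -> TransitionRules:
    """Invert the parabolic-limit definitions at finite step sizes.

    The continuum coefficients are defined as limits of the transition
    probabilities, e.g. ``v_m = (dx/dt)(beta_minus - beta_plus)`` and
    ``D_m = (dx^2 / 2 dt)(beta_minus + beta_plus)``.  At finite
    ``(dx, dy, dt)`` those relations are inverted exactly:

        beta_-/+ = (dt/dx^2) D_m  +/-  (dt/(2 dx)) v_m
        mu_-/+   = (dt/dy^2) D_p  +/-  (dt/(2 dy)) v_p
        gamma    = dt * max(r, 0)        death = dt * max(-r, 0)
        lam      = dt * dy * nu

    The extra ``dy`` in ``lam`` makes the expected per-element removal rate
    ``sum_j lam / dt`` a midpoint quadrature of the continuum loss integral
    ``∫ nu dy``.  Count arguments are converted to densities through the
    site capacity ``K``: ``rho = kappa N / K``, ``e = kappa e_i / K`` and
    ``n(x, y) = kappa n_ij / (K dy)``.

    The returned rules are range-checked on a random sample of attainable
    states; an out-of-range probability raises :class:`InvalidScalingError`
    (the usual fix is to reduce ``dt``).
    """
    dx, dy, dt, K = lattice.dx, lattice.dy, lattice.dt, lattice.site_capacity
    y_of_j = lambda j: lattice.y_min + dy * np.asarray(j, dtype=float)
    to_rho = kappa / K

    def beta_minus(j, N, e):
        y = y_of_j(j)
        return dt / dx**2 * coeffs.D_m(y, N * to_rho, e * to_rho) \
            + dt / (2 * dx) * coeffs.v_m(y, N * to_rho, e * to_rho)

    def beta_plus(j, N, e):
        y = y_of_j(j)
        return dt / dx**2 * coeffs.D_m(y, N * to_rho, e * to_rho) \
            - dt / (2 * dx) * coeffs.v_m(y, N * to_rho, e * to_rho)

    def mu_minus(j, N, e):
        y = y_of_j(j)
        return dt / dy**2 * coeffs.D_p(y, N * to_rho, e * to_rho) \
            + dt / (2 * dy) * coeffs.v_p(y, N * to_rho, e * to_rho)

    def mu_plus(j, N, e):
        y = y_of_j(j)
        return dt / dy**2 * coeffs.D_p(y, N * to_rho, e * to_rho) \
            - dt / (2 * dy) * coeffs.v_p(y, N * to_rho, e * to_rho)

    def gamma(j, N, e):
        return dt * np.maximum(coeffs.r(y_of_j(j), N * to_rho, e * to_rho), 0.0)

    def death(j, N, e):
        return dt * np.maximum(-coeffs.r(y_of_j(j), N * to_rho, e * to_rho), 0.0)

    def lam(j, n_ij):
        return dt * dy * coeffs.nu(y_of_j(j), n_ij * kappa / (K * dy))

    rules = TransitionRules(
        beta_minus=beta_minus, beta_plus=beta_plus,
        mu_minus=mu_minus, mu_plus=mu_plus,
        gamma=gamma, death=death, lam=lam,
    )

    if validate_samples > 0:
        _validate_rules(rules, lattice, validate_samples, validate_seed)
    return rules


def _validate_rules(
    rules: TransitionRules, lattice: LatticeConfig, samples: int, seed: int
) -> None:
    """Range-check each probability on random attainable (j, N, e) states."""
    rng = np.random.default_rng(seed)
    K = lattice.site_capacity
    j = rng.integers(0, lattice.n_y + 1, samples)
    N = rng.integers(0, K + 1, samples).astype(float)
    e = np.minimum(rng.integers(0, K + 1, samples), K - N.astype(int)).clip(0)
    e = e.astype(float)
    named = {
        "beta_minus": rules.beta_minus, "beta_plus": rules.beta_plus,
        "mu_minus": rules.mu_minus, "mu_plus": rules.mu_plus,
        "gamma": rules.gamma, "death": rules.death,
    }
    values = {}
    for name, fn in named.items():
        v = np.asarray(np.broadcast_to(fn(j, N, e), j.shape), dtype=float)
        values[name] = v
        if (v < -1e-12).any() or (v > 1.0 + 1e-12).any():
            k = int(np.argmax(np.maximum(-v, v - 1.0)))
            raise InvalidScalingError(
                f"{name} = {v[k]:.6g} outside [0, 1] at j={j[k]}, N={N[k]:.0f}, "
                f"e={e[k]:.0f} with dx={lattice.dx:.3g}, dy={lattice.dy:.3g}, "
                f"dt={lattice.dt:.3g}; reduce dt"
            )
    total = sum(values.values())
    if (total > 1.0 + 1e-12).any():
        k = int(np.argmax(total))
        raise InvalidScalingError(
            f"event probabilities sum to {total[k]:.6g} > 1 at j={j[k]}, "
            f"N={N[k]:.0f}, e={e[k]:.0f} with dx={lattice.dx:.3g}, "
            f"dy={lattice.dy:.3g}, dt={lattice.dt:.3g}; reduce dt"
        )
    lam = np.asarray(np.broadcast_to(rules.lam(j, N), j.shape), dtype=float)
    if (lam < -1e-12).any():
        raise InvalidScalingError("lam produced a negative probability")
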