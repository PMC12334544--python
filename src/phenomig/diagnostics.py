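"""Post-processing: front tracking, wave speeds, phenotype structure, and
cross-validation of the stochastic lattice model against its continuum limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ibm import EnsembleResult, LatticeConfig
from .pde import Grid, Trajectory, total_density

__all__ = [
    "FrontTrace",
    "front_position",
    "track_front",
    "wave_speed",
    "mean_phenotype",
    "phenotype_entropy",
    "ComparisonReport",
    "compare_ibm_pde",
    "ibm_to_densities",
]


def front_position(rho: np.ndarray, x: np.ndarray, threshold: float = 0.1) -> float:
    """Rightmost downward crossing of ``rho`` through ``threshold``.

    Located by linear interpolation between the bracketing nodes.  Returns
    ``nan`` when the profile never crosses the threshold downward (no
    front is a value, not an error).
    """
    rho = np.asarray(rho, dtype=float)
    above = rho >= threshold
    # downward crossing between node k and k+1
    cross = above[:-1] & ~above[1:]
    if not cross.any():
        return float("nan")
    k = int(np.flatnonzero(cross)[-1])
    r0, r1 = rho[k], rho[k + 1]
    frac = (r0 - threshold) / (r0 - r1)
    return float(x[k] + frac * (x[k + 1] - x[k]))


@dataclass(frozen=True)
class FrontTrace:
    """Front positions over time and the derived speed estimate."""

    times: np.ndarray
    x_star: np.ndarray  # nan where no crossing exists
    threshold: float

    @property
    def speeds(self) -> np.ndarray:
        """Successive difference quotients between defined front positions."""
        ok = np.isfinite(self.x_star)
        t, x = self.times[ok], self.x_star[ok]
        if len(x) < 2:
            return np.array([])
        return np.diff(x) / np.diff(t)


def track_front(traj: Trajectory, grid: Grid, threshold: float = 0.1) -> FrontTrace:
    x_star = np.array([
        front_position(total_density(f.n, grid), grid.x, threshold)
        for f in traj.fields
    ])
    return FrontTrace(times=traj.times, x_star=x_star, threshold=threshold)


def wave_speed(front: FrontTrace, window: float = 0.5) -> tuple[float, float]:
    """Mean and standard deviation of the difference-quotient speeds over a
    trailing time window (fraction of the defined front positions).

    The trailing window discards the initial transient before the profile
    settles into a constant-speed travelling wave.
    """
    if not 0.0 < window <= 1.0:
        raise ValueError("window must lie in (0, 1]")
    ok = np.isfinite(front.x_star)
    t, x = front.times[ok], front.x_star[ok]
    if len(x) < 3:
        raise ValueError(
            "need at least 3 front positions to estimate a speed; run longer"
        )
    speeds = np.diff(x) / np.diff(t)
    n_keep = max(2, int(np.ceil(window * len(speeds))))
    tail = speeds[-n_keep:]
    return float(tail.mean()), float(tail.std())


def mean_phenotype(n: np.ndarray, grid: Grid, density_floor: float = 1e-6) -> np.ndarray:
    """Density-weighted mean phenotype ``ybar(x)``; nan below the floor."""
    if density_floor <= 0:
        raise ValueError("density_floor must be positive")
    rho = total_density(n, grid)
    moment = (n * grid.y[None, :]).sum(axis=-1) * grid.dy
    with np.errstate(invalid="ignore", divide="ignore"):
        ybar = np.where(rho >= density_floor, moment / rho, np.nan)
    return ybar


def phenotype_entropy(n_at_x: np.ndarray, grid: Grid) -> float:
    """Shannon entropy of the local phenotype distribution at one position.

    0 for a point mass, ``ln(n_y + 1)`` for the uniform distribution.
    """
    n_at_x = np.asarray(n_at_x, dtype=float)
    rho = n_at_x.sum() * grid.dy
    if rho <= 0:
        return float("nan")
    p = n_at_x * grid.dy / rho
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def ibm_to_densities(
    ens: EnsembleResult, lattice: LatticeConfig, kappa: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Convert ensemble-mean counts to continuum densities.

    Returns (n, se_n, e, se_e) with ``n = kappa <n_ij> / (K dy)`` and
    ``e = kappa <e_i> / K``.
    """
    K, dy = lattice.site_capacity, lattice.dy
    scale_n = kappa / (K * dy)
    scale_e = kappa / K
    return (ens.mean_n * scale_n, ens.se_n * scale_n,
            ens.mean_e * scale_e, ens.se_e * scale_e)


@dataclass(frozen=True)
class ComparisonReport:
    """Per-save-time discrepancy between ensemble means and the PDE."""

    table: pd.DataFrame  # columns: time, l2_n, linf_n, linf_rho, frac_beyond_4se

    @property
    def max_linf_rho(self) -> float:
        return float(self.table["linf_rho"].max())

    @property
    def max_frac_beyond_4se(self) -> float:
        return float(self.table["frac_beyond_4se"].max())

    def to_json_dict(self) -> dict:
        return {
            "per_time": self.table.to_dict(orient="records"),
            "max_linf_rho": self.max_linf_rho,
            "max_frac_beyond_4se": self.max_frac_beyond_4se,
        }


def compare_ibm_pde(
    ens: EnsembleResult,
    traj: Trajectory,
    lattice: LatticeConfig,
    grid: Grid,
    kappa: float = 1.0,
    se_floor: float | None = None,
) -> ComparisonReport:
    """Discrepancy norms between the lattice ensemble mean and the PDE.

    Requires matching save times and geometry.  The fraction of lattice
    points where the difference exceeds 4 standard errors quantifies how
    far the mean-field closure is from the stochastic truth; ``se_floor``
    (default: the demographic resolution ``kappa/(K dy)`` of a single
    cell) regularises points whose sampled standard error is zero.
    """
    if lattice.shape != grid.shape:
        raise ValueError("lattice and grid geometry mismatch")
    if len(ens.times) != len(traj.times) or not np.allclose(ens.times, traj.times,
                                                            atol=1e-9, rtol=1e-9):
        raise ValueError("save times of the ensemble and the PDE do not match")
    n_ibm, se_n, e_ibm, se_e = ibm_to_densities(ens, lattice, kappa)
    if se_floor is None:
        se_floor = kappa / (lattice.site_capacity * lattice.dy) / max(ens.n_reps, 1)

    rows = []
    for k, t in enumerate(traj.times):
        n_pde = traj.fields[k].n
        diff = n_ibm[k] - n_pde
        se = np.maximum(se_n[k], se_floor)
        rho_ibm = n_ibm[k].sum(axis=-1) * lattice.dy
        rho_pde = total_density(n_pde, grid)
        rows.append({
            "time": float(t),
            "l2_n": float(np.sqrt((diff**2).mean())),
            "linf_n": float(np.abs(diff).max()),
            "linf_rho": float(np.abs(rho_ibm - rho_pde).max()),
            "frac_beyond_4se": float((np.abs(diff) > 4.0 * se).mean()),
        })
    return ComparisonReport(table=pd.DataFrame(rows))


def matched_lattice(grid: Grid, dt: float, site_capacity: int = 100) -> LatticeConfig:
    """A lattice whose phenotype states coincide with the grid's y-cell centres.

    With equal shapes and aligned phenotype values, lattice counts map onto
    grid densities without interpolation.
    """
    y = grid.y
    return LatticeConfig(
        x_min=grid.x_min, x_max=grid.x_max,
        y_min=float(y[0]), y_max=float(y[-1]),
        n_x=grid.n_x, n_y=grid.n_y, dt=dt, site_capacity=site_capacity,
    )


def fields_to_counts(n: np.ndarray, e: np.ndarray, lattice: LatticeConfig,
                     kappa: float = 1.0):
    """Discretise continuum densities into integer lattice counts
    (the inverse of :func:`ibm_to_densities`, rounded to integers)."""
    K, dy = lattice.site_capacity, lattice.dy
    n_counts = np.rint(np.asarray(n) * K * dy / kappa).astype(np.int64)
    e_counts = np.rint(np.asarray(e) * K / kappa).astype(np.int64)
    return np.clip(n_counts, 0, None), np.clip(e_counts, 0, None)
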