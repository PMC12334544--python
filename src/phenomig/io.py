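"""Serialization of trajectories and states: HDF5 for arrays, tidy CSV for
small exports, JSON for summaries.  Every bundle embeds the resolved run
configuration and its hash for provenance."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .ibm import EnsembleResult, IBMState, IBMTrajectory, LatticeConfig
from .pde import Fields, Grid, Trajectory, total_density

__all__ = [
    "write_pde_bundle", "read_pde_bundle",
    "write_ibm_bundle", "read_ibm_bundle",
    "ibm_state_to_frame", "fields_to_frame",
]


def _grid_attrs(h: h5py.File, grid: Grid) -> None:
    h.attrs["x_min"], h.attrs["x_max"] = grid.x_min, grid.x_max
    h.attrs["y_min"], h.attrs["y_max"] = grid.y_min, grid.y_max
    h.attrs["n_x"], h.attrs["n_y"] = grid.n_x, grid.n_y


def write_pde_bundle(
    path: str | Path,
    traj: Trajectory,
    grid: Grid,
    config_json: str = "{}",
    config_hash: str = "",
    preset_name: str = "",
) -> None:
    with h5py.File(path, "w") as h:
        _grid_attrs(h, grid)
        h.attrs["kind"] = "pde"
        h.attrs["config"] = config_json
        h.attrs["config_hash"] = config_hash
        h.attrs["preset"] = preset_name
        h.create_dataset("times", data=traj.times)
        h.create_dataset("n", data=np.stack([f.n for f in traj.fields]))
        h.create_dataset("e", data=np.stack([f.e for f in traj.fields]))
        h.create_dataset(
            "rho", data=np.stack([total_density(f.n, grid) for f in traj.fields])
        )


def read_pde_bundle(path: str | Path) -> tuple[Trajectory, Grid, dict]:
    with h5py.File(path, "r") as h:
        grid = Grid(x_min=float(h.attrs["x_min"]), x_max=float(h.attrs["x_max"]),
                    y_min=float(h.attrs["y_min"]), y_max=float(h.attrs["y_max"]),
                    n_x=int(h.attrs["n_x"]), n_y=int(h.attrs["n_y"]))
        times = h["times"][:]
        n = h["n"][:]
        e = h["e"][:]
        meta = {k: h.attrs[k] for k in ("config", "config_hash", "preset", "kind")}
    fields = [Fields(n=n[k], e=e[k], t=float(times[k])) for k in range(len(times))]
    return Trajectory(times=times, fields=fields), grid, meta


def write_ibm_bundle(
    path: str | Path,
    ens: EnsembleResult,
    lattice: LatticeConfig,
    config_json: str = "{}",
    config_hash: str = "",
    preset_name: str = "",
) -> None:
    with h5py.File(path, "w") as h:
        h.attrs["kind"] = "ibm"
        h.attrs["config"] = config_json
        h.attrs["config_hash"] = config_hash
        h.attrs["preset"] = preset_name
        h.attrs["x_min"], h.attrs["x_max"] = lattice.x_min, lattice.x_max
        h.attrs["y_min"], h.attrs["y_max"] = lattice.y_min, lattice.y_max
        h.attrs["n_x"], h.attrs["n_y"] = lattice.n_x, lattice.n_y
        h.attrs["dt"] = lattice.dt
        h.attrs["site_capacity"] = lattice.site_capacity
        h.attrs["n_reps"] = ens.n_reps
        h.attrs["seed"] = ens.seed
        h.create_dataset("times", data=ens.times)
        h.create_dataset("mean_n", data=ens.mean_n)
        h.create_dataset("se_n", data=ens.se_n)
        h.create_dataset("mean_e", data=ens.mean_e)
        h.create_dataset("se_e", data=ens.se_e)


def read_ibm_bundle(path: str | Path) -> tuple[EnsembleResult, LatticeConfig, dict]:
    with h5py.File(path, "r") as h:
        lattice = LatticeConfig(
            x_min=float(h.attrs["x_min"]), x_max=float(h.attrs["x_max"]),
            y_min=float(h.attrs["y_min"]), y_max=float(h.attrs["y_max"]),
            n_x=int(h.attrs["n_x"]), n_y=int(h.attrs["n_y"]),
            dt=float(h.attrs["dt"]), site_capacity=int(h.attrs["site_capacity"]),
        )
        ens = EnsembleResult(
            times=h["times"][:], mean_n=h["mean_n"][:], se_n=h["se_n"][:],
            mean_e=h["mean_e"][:], se_e=h["se_e"][:],
            n_reps=int(h.attrs["n_reps"]), seed=int(h.attrs["seed"]),
        )
        meta = {k: h.attrs[k] for k in ("config", "config_hash", "preset", "kind")}
    return ens, lattice, meta


def ibm_state_to_frame(state: IBMState, lattice: LatticeConfig) -> pd.DataFrame:
    """Tidy long-format export of one lattice state (t, i, j, x, y, count)."""
    nx1, ny1 = state.n.shape
    i, j = np.meshgrid(np.arange(nx1), np.arange(ny1), indexing="ij")
    return pd.DataFrame({
        "t": state.t,
        "i": i.ravel(), "j": j.ravel(),
        "x": lattice.x[i.ravel()], "y": lattice.y[j.ravel()],
        "count": state.n.ravel(),
    })


def fields_to_frame(fields: Fields, grid: Grid) -> pd.DataFrame:
    nx1, ny1 = fields.n.shape
    i, j = np.meshgrid(np.arange(nx1), np.arange(ny1), indexing="ij")
    return pd.DataFrame({
        "t": fields.t,
        "x": grid.x[i.ravel()], "y": grid.y[j.ravel()],
        "n": fields.n.ravel(),
    })
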