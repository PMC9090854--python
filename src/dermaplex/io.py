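"""File output/input: gridded fields (HDF5), profiles, sweeps and logs (CSV).

Every file embeds the effective config hash and the seed, so any output can
be traced to the exact configuration that produced it. CSV files carry the
provenance in leading ``#`` comment lines and units in their column names.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import GeometryParams, build_unit_cell, classify_nodes
from .transport import SimState

__all__ = [
    "write_fields",
    "read_fields",
    "write_csv",
    "write_profiles",
]


def write_fields(path, state: SimState, grid, config_hash: str, seed: int, extra: dict | None = None) -> None:
    """Write a SimState plus grid coordinates/labels to a self-describing HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = config_hash
        f.attrs["seed"] = seed
        f.attrs["time_s"] = state.time
        f.attrs["geometry_params"] = json.dumps(
            {k: getattr(grid.geom.params, k) for k in GeometryParams.__dataclass_fields__}
        )
        f.attrs["resolution_um"] = (grid.dx, grid.dy, grid.dz)
        for k, v in (extra or {}).items():
            f.attrs[k] = v
        f.create_dataset("C_vs_per_m3", data=state.C_vs)
        f.create_dataset("C_b_per_m3", data=state.C_b)
        f.create_dataset("C_vp_per_m3", data=state.C_vp)
        f.create_dataset("C_ap_per_m3", data=state.C_ap)
        f.create_dataset("labels", data=grid.labels)
        f.create_dataset("x_um", data=grid.x_centers())
        f.create_dataset("y_um", data=grid.y_centers())
        f.create_dataset("z_um", data=grid.z_centers())


def read_fields(path):
    """Reload a saved state; the grid is rebuilt deterministically."""
    with h5py.File(path, "r") as f:
        gp = GeometryParams(**json.loads(f.attrs["geometry_params"]))
        res = tuple(float(v) for v in f.attrs["resolution_um"])
        grid = classify_nodes(build_unit_cell(gp), res)
        state = SimState(
            time=float(f.attrs["time_s"]),
            C_vs=f["C_vs_per_m3"][...],
            C_b=f["C_b_per_m3"][...],
            C_vp=float(f["C_vp_per_m3"][()]),
            C_ap=float(f["C_ap_per_m3"][()]),
        )
        if not np.array_equal(grid.labels, f["labels"][...]):
            raise ValueError(f"stored labels do not match rebuilt grid for {path}")
        meta = dict(f.attrs)
    return state, grid, meta


def write_csv(df: pd.DataFrame, path, config_hash: str, seed: int) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_profiles(profiles, path, config_hash: str, seed: int) -> None:
    frames = [p.to_frame() for p in profiles]
    write_csv(pd.concat(frames, ignore_index=True), path, config_hash, seed)
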