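"""Trajectory and table I/O.

Trajectories travel as plain CSV with columns t, x, y and a small block
of ``#``-prefixed header metadata (units, dt, seed, config hash).  There
is no community standard for 2-D behavior tracks, so this minimal
schema is the interchange format; positions may be declared in either
sim-units or mm and are converted to sim-units on load.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .arena import UNITS_PER_MM
from .simulator import Trajectory

_REQUIRED = ("t", "x", "y")


def save_trajectory(
    traj: Trajectory,
    path: str | Path,
    units: str = "sim",
    seed: Optional[int] = None,
    config_hash: Optional[str] = None,
) -> Path:
    """Write a trajectory as CSV with metadata header lines."""
    if units not in ("sim", "mm"):
        raise ValueError("units must be 'sim' or 'mm'")
    path = Path(path)
    scale = 1.0 if units == "sim" else 1.0 / UNITS_PER_MM
    df = pd.DataFrame(
        {
            "t": traj.times,
            "x": traj.positions[:, 0] * scale,
            "y": traj.positions[:, 1] * scale,
        }
    )
    with path.open("w") as fh:
        fh.write("# wigwag trajectory\n")
        fh.write(f"# units: {units}\n")
        fh.write(f"# dt: {traj.dt!r}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if config_hash is not None:
            fh.write(f"# config: {config_hash}\n")
        df.to_csv(fh, index=False)
    return path


def load_trajectory(path: str | Path, units: Optional[str] = None) -> Trajectory:
    """Read a trajectory CSV back into sim-units.

    ``units`` overrides the ``# units:`` header; without either, values
    are taken to be sim-units already.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    k, v = stripped.split(":", 1)
                    meta[k.strip()] = v.strip()
            else:
                body_lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(body_lines)), float_precision="round_trip")
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"trajectory file {path} is missing column {col!r}")
    for col in _REQUIRED:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"column {col!r} in {path} contains non-numeric values")
    t = df["t"].to_numpy(dtype=float)
    if len(t) >= 2:
        dts = np.diff(t)
        if dts.min() <= 0 or np.ptp(dts) > 1e-9:
            raise ValueError(f"column 't' in {path} is not a uniform increasing grid")
    units = units or meta.get("units", "sim")
    if units not in ("sim", "mm"):
        raise ValueError(f"unknown units {units!r} (expected 'sim' or 'mm')")
    scale = 1.0 if units == "sim" else UNITS_PER_MM
    pos = df[["x", "y"]].to_numpy(dtype=float) * scale
    return Trajectory(times=t, positions=pos)


def save_table(df: pd.DataFrame, path: str | Path, **header: object) -> Path:
    """Write a DataFrame as CSV with optional ``# key: value`` headers."""
    path = Path(path)
    with path.open("w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)
    return path


def save_grid(grid, path: str | Path, **header: object) -> Path:
    """Write an occupancy grid's density matrix as a CSV matrix."""
    path = Path(path)
    with path.open("w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        fh.write(f"# cell_mm: {grid.cell_mm}\n")
        fh.write(f"# bandwidth_mm: {grid.bandwidth_mm!r}\n")
        pd.DataFrame(grid.density, index=grid.y_centers, columns=grid.x_centers).to_csv(fh)
    return path
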