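"""Snapshot and ledger output.

3D concentration grids are written as ASCII-encoded NRRD (detached-header
style in a single file) carrying the grid origin and spacing, so snapshots
are self-describing and human-inspectable; 2D depth-averaged maps and
wave-front time series go to CSV.  Concentrations are in mM relative to
free volume; coordinates in um; times in ms.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import ECSGrid

__all__ = ["write_snapshot", "read_snapshot", "depth_average", "write_wave_front"]

_UNITS_NOTE = "mM relative to free volume; coordinates um"


def write_snapshot(conc: np.ndarray, grid: ECSGrid, species: str, path,
                   fmt: str = "nrrd"):
    """Write one species' field.  ``fmt``: ``"nrrd"`` for the full 3D grid,
    ``"csv"`` for the depth-averaged (over z) 2D map."""
    if not species:
        raise ValueError("species name must be non-empty")
    conc = np.asarray(conc)
    if conc.shape != grid.shape:
        raise ValueError(f"field shape {conc.shape} does not match grid {grid.shape}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "nrrd":
        _write_nrrd(conc, grid, species, path)
    elif fmt == "csv":
        df = depth_average(conc, grid)
        with open(path, "w") as f:
            f.write(f"# species: {species}; units: {_UNITS_NOTE}\n")
            df.to_csv(f, index=False)
    else:
        raise ValueError(f"unknown snapshot format {fmt!r}")
    return path


def _write_nrrd(conc, grid, species, path):
    header = [
        "NRRD0004",
        f"# species: {species}",
        f"# units: {_UNITS_NOTE}",
        "type: double",
        "dimension: 3",
        f"sizes: {grid.nx} {grid.ny} {grid.nz}",
        "encoding: ascii",
        "space dimension: 3",
        f"space origin: ({grid.xlo},{grid.ylo},{grid.zlo})",
        f"space directions: ({grid.dx},0,0) (0,{grid.dy},0) (0,0,{grid.dz})",
    ]
    buf = _io.StringIO()
    # NRRD lists the fastest axis first; sizes nx ny nz -> x fastest
    np.savetxt(buf, conc.ravel(order="F")[None, :], fmt="%.17g")
    with open(path, "w") as f:
        f.write("\n".join(header) + "\n\n" + buf.getvalue())


def read_snapshot(path):
    """Read an ASCII NRRD snapshot back; returns ``(array, meta)`` with
    ``meta`` holding sizes, space origin and spacing, and comment fields."""
    with open(path) as f:
        text = f.read()
    head, _, data = text.partition("\n\n")
    lines = head.splitlines()
    if not lines[0].startswith("NRRD"):
        raise ValueError(f"{path}: not an NRRD file")
    meta = {"comments": []}
    for line in lines[1:]:
        if line.startswith("#"):
            meta["comments"].append(line[1:].strip())
        elif ":" in line:
            k, v = line.split(":", 1)
            meta[k.strip()] = v.strip()
    sizes = tuple(int(s) for s in meta["sizes"].split())
    origin = tuple(float(s) for s in meta["space origin"].strip("()").split(","))
    spacing = tuple(
        float(v.strip("()").split(",")[i])
        for i, v in enumerate(meta["space directions"].split())
    )
    arr = np.asarray(data.split(), dtype=float).reshape(sizes, order="F")
    meta["origin"] = origin
    meta["spacing"] = spacing
    return arr, meta


def depth_average(conc: np.ndarray, grid: ECSGrid) -> pd.DataFrame:
    """Average the field over z; long-format DataFrame with x, y (voxel
    centers, um) and the mean concentration."""
    mean = np.asarray(conc).mean(axis=2)
    x, y, _ = grid.axes_centers()
    X, Y = np.meshgrid(x, y, indexing="ij")
    return pd.DataFrame(
        {"x_um": X.ravel(), "y_um": Y.ravel(), "mean_mM": mean.ravel()}
    )


def write_wave_front(times_ms, radii_um, path):
    """Wave-front time series CSV: t_ms, radius_um."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"t_ms": times_ms, "radius_um": radii_um}).to_csv(
        path, index=False
    )
    return path
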