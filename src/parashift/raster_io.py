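"""Plain-text raster I/O.

Rasters are exchanged as ESRI ASCII grids (``.asc``) — a widely supported,
human-readable format carrying the full georeference in its header. A
:class:`~parashift.grids.ClimateStack` is written as a directory of one
``.asc`` per layer plus a ``stack.json`` sidecar recording layer order and
grid metadata.

ASC files are stored north-up (first data row = northern edge); parashift
arrays are south-up, so readers/writers flip rows.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import numpy as np

from .errors import ConfigurationError, FormatError
from .grids import ClimateStack, GridSpec

__all__ = ["write_ascii_grid", "read_ascii_grid", "write_stack", "read_stack"]


def write_ascii_grid(array: np.ndarray, grid: GridSpec, path) -> Path:
    """Write a single layer as an ESRI ASCII grid (north-up)."""
    array = np.asarray(array)
    if array.shape != grid.shape:
        raise ConfigurationError("array shape does not match grid")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.lon_min!r}\n"
        f"yllcorner {grid.lat_min!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata_value!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, array[::-1], fmt="%.10g")
    return path


def read_ascii_grid(path) -> Tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; returns (south-up array, GridSpec)."""
    path = Path(path)
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                break
            meta[parts[0].lower()] = parts[1]
            pos = fh.tell()
        fh.seek(pos)
        try:
            n_cols = int(meta["ncols"])
            n_rows = int(meta["nrows"])
            lon_min = float(meta["xllcorner"])
            lat_min = float(meta["yllcorner"])
            cell = float(meta["cellsize"])
        except KeyError as exc:
            raise FormatError(f"{path}: missing ASC header field {exc}") from None
        nodata = float(meta.get("nodata_value", -9999.0))
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    if data.shape != (n_rows, n_cols):
        raise FormatError(
            f"{path}: data shape {data.shape} does not match header "
            f"({n_rows}, {n_cols})"
        )
    grid = GridSpec(
        lon_min=lon_min,
        lat_min=lat_min,
        lon_max=lon_min + n_cols * cell,
        lat_max=lat_min + n_rows * cell,
        cell_size=cell,
        n_rows=n_rows,
        n_cols=n_cols,
        nodata_value=nodata,
    )
    return data[::-1].copy(), grid


def write_stack(stack: ClimateStack, directory) -> Path:
    """Write a climate stack as <directory>/<layer>.asc + stack.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in stack.layers.items():
        write_ascii_grid(arr, stack.grid, directory / f"{name}.asc")
    meta = {
        "layers": stack.layer_names,
        "grid": {
            "lon_min": stack.grid.lon_min,
            "lat_min": stack.grid.lat_min,
            "lon_max": stack.grid.lon_max,
            "lat_max": stack.grid.lat_max,
            "cell_size": stack.grid.cell_size,
            "n_rows": stack.grid.n_rows,
            "n_cols": stack.grid.n_cols,
            "nodata_value": stack.grid.nodata_value,
        },
    }
    with open(directory / "stack.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return directory


def read_stack(directory) -> ClimateStack:
    directory = Path(directory)
    meta_path = directory / "stack.json"
    if not meta_path.exists():
        raise FormatError(f"{directory}: no stack.json sidecar")
    with open(meta_path) as fh:
        meta = json.load(fh)
    grid = GridSpec(**meta["grid"])
    layers = {}
    mask = np.ones(grid.shape, dtype=bool)
    for name in meta["layers"]:
        arr, g = read_ascii_grid(directory / f"{name}.asc")
        if not g.same_georeference(grid):
            raise FormatError(f"layer '{name}' georeference differs from sidecar")
        layers[name] = arr
        mask &= arr != grid.nodata_value
    return ClimateStack(grid=grid, layers=layers, mask=mask)
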