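"""Georeferenced grids and climate predictor stacks.

All rasters in parashift share one convention: a regular lon/lat grid
(WGS84 decimal degrees) described by a :class:`GridSpec`. Arrays are indexed
``[row, col]`` with **row 0 at the southern edge**, so that cell ``(i, j)``
covers the half-open box

    [lon_min + j*cell, lon_min + (j+1)*cell) x [lat_min + i*cell, lat_min + (i+1)*cell)

A :class:`ClimateStack` bundles named layers (bio1..bio19, derived layers such
as host suitability) on one grid, plus a boolean validity mask. Masked-out
cells carry the grid's nodata value in every layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np

from .errors import ConfigurationError

__all__ = ["GridSpec", "ClimateStack", "make_grid"]

_DIVISIBILITY_TOL = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """Georeference contract shared by all layers of one analysis.

    Parameters are in decimal degrees; ``nodata_value`` is the sentinel
    written into invalid cells of float rasters.
    """

    lon_min: float
    lat_min: float
    lon_max: float
    lat_max: float
    cell_size: float
    n_rows: int
    n_cols: int
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ConfigurationError(
                f"extent must be ordered: lon {self.lon_min}..{self.lon_max}, "
                f"lat {self.lat_min}..{self.lat_max}"
            )
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ConfigurationError("grid must have positive dimensions")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_index(self, lon, lat) -> Tuple[np.ndarray, np.ndarray]:
        """Map points to (row, col) under the half-open cell convention."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.cell_size).astype(int)
        row = np.floor((lat - self.lat_min) / self.cell_size).astype(int)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        """Half-open membership: points on the max edges are outside."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon < self.lon_max)
            & (lat >= self.lat_min)
            & (lat < self.lat_max)
        )

    def cell_center(self, row, col) -> Tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.lon_min + (col + 0.5) * self.cell_size
        lat = self.lat_min + (row + 0.5) * self.cell_size
        return lon, lat

    def same_georeference(self, other: "GridSpec") -> bool:
        return (
            np.isclose(self.lon_min, other.lon_min)
            and np.isclose(self.lat_min, other.lat_min)
            and np.isclose(self.cell_size, other.cell_size)
            and self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
        )


def make_grid(extent: Iterable[float], cell_size: float,
              nodata_value: float = -9999.0) -> GridSpec:
    """Build a :class:`GridSpec` from ``(lon_min, lat_min, lon_max, lat_max)``.

    ``cell_size`` must divide both spans to within 1e-9 of a whole number of
    cells, otherwise a :class:`ConfigurationError` is raised.
    """
    lon_min, lat_min, lon_max, lat_max = (float(v) for v in extent)
    if not (lon_min < lon_max and lat_min < lat_max):
        raise ConfigurationError("extent bounds must be ordered")
    if cell_size <= 0:
        raise ConfigurationError("cell_size must be positive")

    def _n_cells(span: float) -> int:
        n = span / cell_size
        n_round = round(n)
        if n_round < 1 or abs(n - n_round) > _DIVISIBILITY_TOL * max(1.0, abs(n)):
            raise ConfigurationError(
                f"cell_size {cell_size} does not divide span {span}"
            )
        return int(n_round)

    n_cols = _n_cells(lon_max - lon_min)
    n_rows = _n_cells(lat_max - lat_min)
    return GridSpec(lon_min, lat_min, lon_max, lat_max, cell_size,
                    n_rows, n_cols, nodata_value)


@dataclass
class ClimateStack:
    """Named predictor layers on one grid.

    ``layers`` preserves insertion order (the canonical bio1..bio19 order when
    built by the synthetic world). ``mask`` is True on valid cells; invalid
    cells hold ``grid.nodata_value`` in every layer.
    """

    grid: GridSpec
    layers: Dict[str, np.ndarray] = field(default_factory=dict)
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ConfigurationError("mask shape does not match grid")
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ConfigurationError(
                    f"layer '{name}' shape {arr.shape} != grid {self.grid.shape}"
                )
            arr = arr.copy()
            arr[~self.mask] = self.grid.nodata_value
            self.layers[name] = arr

    @property
    def layer_names(self) -> list:
        return list(self.layers.keys())

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def layer(self, name: str) -> np.ndarray:
        try:
            return self.layers[name]
        except KeyError:
            raise ConfigurationError(f"layer '{name}' not in stack "
                                     f"(have {self.layer_names})") from None

    def add_layer(self, name: str, values: np.ndarray) -> None:
        if name in self.layers:
            raise ConfigurationError(f"layer '{name}' already present")
        values = np.asarray(values, dtype=float).copy()
        if values.shape != self.grid.shape:
            raise ConfigurationError(f"layer '{name}' shape mismatch")
        values[~self.mask] = self.grid.nodata_value
        self.layers[name] = values

    def values_at(self, lon, lat, names: Optional[Iterable[str]] = None) -> np.ndarray:
        """Extract layer values at point locations -> array (n_points, n_layers).

        Points outside the extent or on invalid cells yield NaN rows.
        """
        names = list(names) if names is not None else self.layer_names
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        inside = self.grid.contains(lon, lat)
        row, col = self.grid.cell_index(np.clip(lon, self.grid.lon_min, None),
                                        np.clip(lat, self.grid.lat_min, None))
        row = np.clip(row, 0, self.grid.n_rows - 1)
        col = np.clip(col, 0, self.grid.n_cols - 1)
        ok = inside & self.mask[row, col]
        out = np.full((lon.size, len(names)), np.nan)
        for k, name in enumerate(names):
            out[ok, k] = self.layer(name)[row[ok], col[ok]]
        return out

    def valid_matrix(self, names: Optional[Iterable[str]] = None) -> np.ndarray:
        """Stack valid-cell values -> array (n_valid, n_layers)."""
        names = list(names) if names is not None else self.layer_names
        return np.column_stack([self.layer(n)[self.mask] for n in names])

    def copy(self) -> "ClimateStack":
        return ClimateStack(
            grid=self.grid,
            layers={k: v.copy() for k, v in self.layers.items()},
            mask=self.mask.copy(),
        )

    def subset(self, names: Iterable[str]) -> "ClimateStack":
        names = list(names)
        return ClimateStack(
            grid=self.grid,
            layers={n: self.layer(n).copy() for n in names},
            mask=self.mask.copy(),
        )
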