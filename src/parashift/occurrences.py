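"""Occurrence records: reading, deduplication, extent clipping, spatial
thinning, and background (pseudo-absence) point selection.

Presence-only occurrence databases are regionally over-sampled; retaining one
randomly chosen record per species per thinning-grid cell (0.25 degrees by
default) balances the spatial representation before model fitting. Background
points stand in for absences: they are sampled uniformly over the valid cells
of the predictor stack (10,000 by default) and placed at cell centers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, FormatError
from .grids import ClimateStack, GridSpec

__all__ = [
    "OccurrenceSet",
    "BackgroundSet",
    "read_occurrences",
    "deduplicate",
    "clip_to_extent",
    "thin_per_cell",
    "sample_background",
]

logger = logging.getLogger(__name__)

STAGES = ("raw", "deduplicated", "clipped", "thinned")


@dataclass
class OccurrenceSet:
    """Point records (species, lon, lat, source) with a processing-stage tag."""

    table: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        required = ["species", "lon", "lat"]
        for col in required:
            if col not in self.table.columns:
                raise FormatError(f"occurrence table lacks column '{col}'")
        if "source" not in self.table.columns:
            self.table = self.table.assign(source="unknown")
        self.table = self.table[["species", "lon", "lat", "source"]].reset_index(
            drop=True
        )
        if self.stage not in STAGES:
            raise ConfigurationError(f"unknown stage '{self.stage}'")

    @classmethod
    def from_records(
        cls,
        records: Iterable[Tuple[str, float, float, str]],
        stage: str = "raw",
    ) -> "OccurrenceSet":
        df = pd.DataFrame(records, columns=["species", "lon", "lat", "source"])
        return cls(df, stage=stage)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def species(self) -> List[str]:
        return list(pd.unique(self.table["species"]))

    def coords(self) -> Tuple[np.ndarray, np.ndarray]:
        return (
            self.table["lon"].to_numpy(float),
            self.table["lat"].to_numpy(float),
        )

    def for_species(self, name: str) -> "OccurrenceSet":
        sub = self.table[self.table["species"] == name].reset_index(drop=True)
        return OccurrenceSet(sub, stage=self.stage)

    def to_csv(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False)
        return path


@dataclass
class BackgroundSet:
    """Pseudo-absence points (lon, lat), all on valid predictor cells."""

    points: np.ndarray  # shape (n, 2): lon, lat

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    @property
    def count(self) -> int:
        return self.points.shape[0]

    def coords(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.points[:, 0], self.points[:, 1]


def read_occurrences(path) -> OccurrenceSet:
    """Read a CSV with columns species, lon, lat (+ optional source).

    Rows with unparseable or non-finite coordinates are skipped with a
    logged warning; a missing required column is a :class:`FormatError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file without header") from None
    for col in ("species", "lon", "lat"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad = ~(np.isfinite(lon) & np.isfinite(lat)) | df["species"].isna()
    for idx in df.index[bad]:
        logger.warning("%s: skipping malformed row %d: %s",
                       path, idx + 2, df.loc[idx].to_dict())
    clean = pd.DataFrame(
        {
            "species": df["species"][~bad],
            "lon": lon[~bad].astype(float),
            "lat": lat[~bad].astype(float),
            "source": df["source"][~bad] if "source" in df.columns else str(path),
        }
    ).reset_index(drop=True)
    return OccurrenceSet(clean, stage="raw")


def deduplicate(occ: OccurrenceSet) -> OccurrenceSet:
    """Drop exact duplicates on (species, lon, lat), keeping first occurrence."""
    table = occ.table.drop_duplicates(
        subset=["species", "lon", "lat"], keep="first"
    ).reset_index(drop=True)
    return OccurrenceSet(table, stage="deduplicated")


def clip_to_extent(occ: OccurrenceSet, grid: GridSpec) -> OccurrenceSet:
    """Keep records inside the study extent (half-open: max edges excluded)."""
    lon, lat = occ.coords()
    keep = grid.contains(lon, lat)
    return OccurrenceSet(occ.table[keep].reset_index(drop=True), stage="clipped")


def _thin_cell_index(
    lon: np.ndarray, lat: np.ndarray, origin: Tuple[float, float], cell: float
) -> np.ndarray:
    """Integer thinning-cell ids, origin anchored at the extent lower-left."""
    col = np.floor((lon - origin[0]) / cell).astype(np.int64)
    row = np.floor((lat - origin[1]) / cell).astype(np.int64)
    return row * 10_000_000 + col  # collision-free for any realistic grid


def thin_per_cell(
    occ: OccurrenceSet,
    thin_cell_size: float = 0.25,
    seed: int = 0,
    origin: Optional[Tuple[float, float]] = None,
) -> OccurrenceSet:
    """Retain one random record per species per thinning-grid cell.

    The thinning grid is anchored at ``origin`` (default: the floor of the
    data extent, which coincides with the study extent's lower-left corner
    when the data were clipped first).
    """
    if thin_cell_size <= 0:
        raise ConfigurationError("thin_cell_size must be positive")
    if len(occ) == 0:
        return OccurrenceSet(occ.table.copy(), stage="thinned")
    lon, lat = occ.coords()
    if origin is None:
        origin = (
            float(np.floor(lon.min() / thin_cell_size) * thin_cell_size),
            float(np.floor(lat.min() / thin_cell_size) * thin_cell_size),
        )
    cells = _thin_cell_index(lon, lat, origin, thin_cell_size)
    rng = np.random.default_rng(seed)
    df = occ.table.assign(_cell=cells)
    kept_idx: List[int] = []
    # iterate groups in a deterministic order so the seeded draws reproduce
    for (_, _), group in df.groupby(["species", "_cell"], sort=True):
        kept_idx.append(int(rng.choice(group.index.to_numpy())))
    kept_idx.sort()
    out = occ.table.loc[kept_idx].reset_index(drop=True)
    return OccurrenceSet(out, stage="thinned")


def thinning_report(before: OccurrenceSet, after: OccurrenceSet) -> Dict:
    """Per-species record counts before and after thinning (JSON-ready)."""
    rep = {}
    for sp in before.species:
        rep[sp] = {
            "before": int((before.table["species"] == sp).sum()),
            "after": int((after.table["species"] == sp).sum()),
        }
    return rep


def drop_nodata_points(occ: OccurrenceSet, stack: ClimateStack) -> OccurrenceSet:
    """Drop presence points on nodata cells (count logged)."""
    lon, lat = occ.coords()
    inside = stack.grid.contains(lon, lat)
    row, col = stack.grid.cell_index(lon, lat)
    ok = inside.copy()
    ok[inside] = stack.mask[row[inside], col[inside]]
    dropped = int((~ok).sum())
    if dropped:
        logger.info("dropping %d occurrence(s) on nodata cells", dropped)
    return OccurrenceSet(occ.table[ok].reset_index(drop=True), stage=occ.stage)


def sample_background(
    stack: ClimateStack, n: int = 10_000, seed: int = 0
) -> BackgroundSet:
    """Sample ``n`` background points uniformly over valid cells.

    Cells are drawn without replacement while ``n`` does not exceed the number
    of valid cells (with replacement otherwise); points sit at cell centers,
    where the predictors are defined.
    """
    valid = np.flatnonzero(stack.mask.ravel())
    if valid.size == 0:
        raise DegenerateInputError("stack has no valid cells")
    rng = np.random.default_rng(seed)
    replace = n > valid.size
    idx = rng.choice(valid, size=n, replace=replace)
    row, col = np.unravel_index(idx, stack.grid.shape)
    lon, lat = stack.grid.cell_center(row, col)
    return BackgroundSet(np.column_stack([lon, lat]))
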