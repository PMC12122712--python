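"""Model evaluation: train/validation split, AUC, max(sens+spec) threshold,
binary range maps and range saturation.

Specificity is computed against background points standing in for absences —
the convention of presence-only SDM evaluation, where true absences do not
exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.stats import rankdata

from .errors import ConfigurationError, InsufficientDataError
from .grids import GridSpec
from .occurrences import OccurrenceSet

__all__ = [
    "EvaluationReport",
    "BinaryRangeMap",
    "split_train_validation",
    "auc",
    "max_sens_spec_threshold",
    "binarize",
    "range_saturation",
]


@dataclass
class EvaluationReport:
    """Validation metrics at the max(sensitivity+specificity) threshold."""

    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    n_presence: int
    n_background: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "auc", "threshold", "sensitivity", "specificity",
            "tp", "fp", "tn", "fn", "n_presence", "n_background",
        )}


@dataclass
class BinaryRangeMap:
    """Boolean suitable/unsuitable raster plus its generating threshold.

    ``values`` is int8: 1 suitable, 0 unsuitable, -1 nodata.
    """

    grid: GridSpec
    values: np.ndarray
    threshold: float
    source_model: str = ""

    NODATA: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != self.grid.shape:
            raise ConfigurationError("range map shape does not match grid")

    @property
    def mask(self) -> np.ndarray:
        return self.values != self.NODATA

    @property
    def suitable(self) -> np.ndarray:
        return self.values == 1

    @property
    def n_suitable(self) -> int:
        return int((self.values == 1).sum())


def split_train_validation(
    occ: OccurrenceSet, fraction: float = 0.8, seed: int = 0
) -> Tuple[OccurrenceSet, OccurrenceSet]:
    """Seeded uniform split into round(fraction*n) training records + rest."""
    n = len(occ)
    if n < 5:
        raise InsufficientDataError(f"need at least 5 records, have {n}")
    if not 0 < fraction < 1:
        raise ConfigurationError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fraction * n))
    train_idx = np.sort(perm[:n_train])
    val_idx = np.sort(perm[n_train:])
    train = OccurrenceSet(occ.table.iloc[train_idx].reset_index(drop=True),
                          stage=occ.stage)
    val = OccurrenceSet(occ.table.iloc[val_idx].reset_index(drop=True),
                        stage=occ.stage)
    return train, val


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ConfigurationError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def _confusion(p: np.ndarray, b: np.ndarray, tau: float):
    tp = int((p >= tau).sum())
    fn = p.size - tp
    fp = int((b >= tau).sum())
    tn = b.size - fp
    return tp, fp, tn, fn


def max_sens_spec_threshold(
    presence_scores: np.ndarray, background_scores: np.ndarray
) -> Tuple[float, EvaluationReport]:
    """Threshold maximizing sensitivity + specificity.

    Candidates are midpoints between adjacent sorted unique scores (plus the
    extremes' immediate neighborhood via the unique scores themselves being
    bracketed); ties break toward the smaller threshold, i.e. the more
    inclusive predicted range. A point scoring exactly the threshold counts
    as suitable (>=).
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ConfigurationError("both score sets must be non-empty")
    uniq = np.unique(np.concatenate([p, b]))
    if uniq.size == 1:
        candidates = np.array([uniq[0]])
    else:
        candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_tau, best_sum = None, -np.inf
    for tau in candidates:  # ascending: first maximizer = smallest tau
        tp, fp, tn, fn = _confusion(p, b, tau)
        s = tp / (tp + fn) + tn / (tn + fp)
        if s > best_sum + 1e-12:
            best_sum, best_tau = s, float(tau)
    tp, fp, tn, fn = _confusion(p, b, best_tau)
    report = EvaluationReport(
        auc=auc(p, b),
        threshold=best_tau,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        tp=tp, fp=fp, tn=tn, fn=fn,
        n_presence=p.size, n_background=b.size,
    )
    return best_tau, report


def binarize(suitability: np.ndarray, grid: GridSpec, threshold: float,
             source_model: str = "") -> BinaryRangeMap:
    """Suitable iff suitability >= threshold; nodata propagates."""
    if not 0 < threshold < 1:
        raise ConfigurationError("threshold must be in (0, 1)")
    suit = np.asarray(suitability, dtype=float)
    if suit.shape != grid.shape:
        raise ConfigurationError("suitability shape does not match grid")
    nodata = suit == grid.nodata_value
    values = np.where(suit >= threshold, 1, 0).astype(np.int8)
    values[nodata] = BinaryRangeMap.NODATA
    return BinaryRangeMap(grid=grid, values=values, threshold=threshold,
                          source_model=source_model)


def range_saturation(
    occ: OccurrenceSet, brm: BinaryRangeMap
) -> Tuple[float, float]:
    """(point saturation, cell saturation).

    Point saturation: fraction of occurrence points lying in suitable cells
    (points outside the extent or on nodata cells count as unsuitable).
    Cell saturation: fraction of valid cells that are suitable.
    """
    if len(occ) == 0:
        raise ConfigurationError("empty occurrence set")
    lon, lat = occ.coords()
    inside = brm.grid.contains(lon, lat)
    row, col = brm.grid.cell_index(lon, lat)
    hits = np.zeros(len(occ), dtype=bool)
    hits[inside] = brm.values[row[inside], col[inside]] == 1
    point_sat = float(hits.mean())
    n_valid = int(brm.mask.sum())
    cell_sat = float(brm.n_suitable / n_valid) if n_valid else 0.0
    return point_sat, cell_sat
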