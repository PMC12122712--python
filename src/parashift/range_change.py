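"""Range-change classification between current and future binary maps.

Each valid cell gets the integer code ``current - 2 * future`` with
current, future in {0, 1}:

=====  =============================================
code   meaning
=====  =============================================
 0     still unsuitable (unsuitable now and later)
-2     expansion (newly suitable in the future)
 1     contraction (currently suitable, lost later)
-1     persistence (suitable in both periods)
=====  =============================================

Percentages are relative to the *current* range size (contraction +
persistence cells), so expansion can exceed 100% when the future range more
than doubles. An optional cos-latitude weighting approximates true areas on
the geographic grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .grids import GridSpec
from .model_eval import BinaryRangeMap

__all__ = ["RangeChangeMap", "ChangeSummary", "encode_change",
           "summarize_change", "change_report"]

CODE_STILL_UNSUITABLE = 0
CODE_EXPANSION = -2
CODE_CONTRACTION = 1
CODE_PERSISTENCE = -1
NODATA_CODE = 9

LEGEND = {
    CODE_STILL_UNSUITABLE: "still unsuitable",
    CODE_EXPANSION: "expansion",
    CODE_CONTRACTION: "contraction",
    CODE_PERSISTENCE: "persistence",
}


@dataclass
class RangeChangeMap:
    """Integer-coded change raster over {0, -2, 1, -1} (9 = nodata)."""

    grid: GridSpec
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.shape != self.grid.shape:
            raise ConfigurationError("codes shape does not match grid")
        bad = ~np.isin(self.codes, list(LEGEND) + [NODATA_CODE])
        if bad.any():
            raise ConfigurationError("invalid range-change codes present")

    @property
    def mask(self) -> np.ndarray:
        return self.codes != NODATA_CODE

    def decode(self):
        """Recover (current, future) binary maps from the codes."""
        cur = np.where(self.mask, (self.codes == CODE_CONTRACTION)
                       | (self.codes == CODE_PERSISTENCE), False)
        fut = np.where(self.mask, (self.codes == CODE_EXPANSION)
                       | (self.codes == CODE_PERSISTENCE), False)
        return cur, fut


@dataclass
class ChangeSummary:
    """Cell counts and percentages for one current/future comparison.

    Percentages are None (undefined) when the current range is empty.
    """

    n_still_unsuitable: float
    n_expansion: float
    n_contraction: float
    n_persistence: float
    expansion_pct: Optional[float]
    contraction_pct: Optional[float]
    latitude_weighted: bool = False

    @property
    def current_range_size(self) -> float:
        return self.n_contraction + self.n_persistence

    @property
    def future_range_size(self) -> float:
        return self.n_expansion + self.n_persistence

    def to_dict(self) -> Dict:
        return {
            "n_still_unsuitable": self.n_still_unsuitable,
            "n_expansion": self.n_expansion,
            "n_contraction": self.n_contraction,
            "n_persistence": self.n_persistence,
            "current_range_size": self.current_range_size,
            "future_range_size": self.future_range_size,
            "expansion_pct": self.expansion_pct,
            "contraction_pct": self.contraction_pct,
            "latitude_weighted": self.latitude_weighted,
        }


def encode_change(current: BinaryRangeMap, future: BinaryRangeMap) -> RangeChangeMap:
    """Per-cell code = current - 2 * future; nodata in either input propagates."""
    if not current.grid.same_georeference(future.grid):
        raise ConfigurationError("current and future maps are on different grids")
    valid = current.mask & future.mask
    cur = current.values.astype(np.int16)
    fut = future.values.astype(np.int16)
    codes = np.where(valid, cur - 2 * fut, NODATA_CODE).astype(np.int16)
    return RangeChangeMap(grid=current.grid, codes=codes)


def summarize_change(rcm: RangeChangeMap,
                     latitude_weighted: bool = False) -> ChangeSummary:
    """Count cells per code; percentages relative to the current range size.

    With ``latitude_weighted`` each cell counts cos(latitude of its center),
    approximating its true area share on the lon/lat grid.
    """
    if latitude_weighted:
        w = np.cos(np.deg2rad(rcm.grid.lat_centers()))[:, None]
        weights = np.broadcast_to(w, rcm.grid.shape)
    else:
        weights = np.ones(rcm.grid.shape)

    def wcount(code: int) -> float:
        sel = rcm.codes == code
        return float(weights[sel].sum())

    n0 = wcount(CODE_STILL_UNSUITABLE)
    ne = wcount(CODE_EXPANSION)
    nc = wcount(CODE_CONTRACTION)
    np_ = wcount(CODE_PERSISTENCE)
    current = nc + np_
    if current > 0:
        exp_pct = 100.0 * ne / current
        con_pct = 100.0 * nc / current
    else:
        exp_pct = con_pct = None
    return ChangeSummary(
        n_still_unsuitable=n0, n_expansion=ne, n_contraction=nc,
        n_persistence=np_, expansion_pct=exp_pct, contraction_pct=con_pct,
        latitude_weighted=latitude_weighted,
    )


def change_report(summaries: Dict[tuple, ChangeSummary]) -> pd.DataFrame:
    """Long-format table (ssp, timeline, metric, value) from per-scenario
    summaries keyed by (ssp, timeline)."""
    rows: List[Dict] = []
    for (ssp, timeline), summary in summaries.items():
        for metric, value in summary.to_dict().items():
            if metric == "latitude_weighted":
                continue
            rows.append({"ssp": ssp, "timeline": timeline,
                         "metric": metric, "value": value})
    return pd.DataFrame(rows, columns=["ssp", "timeline", "metric", "value"])
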