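"""Projection of fitted models onto future climate stacks and ensemble
averaging across general circulation models (GCMs).

Continuous suitability is averaged across the GCMs within each SSP x timeline
*before* thresholding (no binary majority voting), which preserves gradual
inter-model disagreement instead of quantizing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .grids import ClimateStack, GridSpec
from .maxent import MaxentModel, predict_suitability

__all__ = ["ScenarioGrid", "project_model", "ensemble_mean"]

HOST_LAYER = "host_suitability"


def project_model(
    model: MaxentModel,
    future_stack: ClimateStack,
    host_future: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Predict suitability on a future stack (training-range clamping on).

    For a host-conditioned model, ``host_future`` supplies the host
    suitability layer for the scenario (either the host model re-projected
    under the same scenario, or the current host layer when the host is held
    static). It overrides any host layer already in the stack.
    """
    stack = future_stack
    if HOST_LAYER in model.variables:
        if host_future is not None:
            stack = future_stack.copy()
            if HOST_LAYER in stack:
                del stack.layers[HOST_LAYER]
            stack.add_layer(HOST_LAYER, host_future)
        elif HOST_LAYER not in future_stack:
            raise ConfigurationError(
                "host-conditioned model needs a host suitability layer "
                "(pass host_future or include it in the stack)"
            )
    return predict_suitability(model, stack, clamp=True)


def ensemble_mean(rasters: Sequence[np.ndarray], grid: GridSpec) -> np.ndarray:
    """Cellwise arithmetic mean; a cell is nodata if any member is nodata."""
    if len(rasters) == 0:
        raise ConfigurationError("ensemble needs at least one raster")
    arrs = []
    for r in rasters:
        r = np.asarray(r, dtype=float)
        if r.shape != grid.shape:
            raise ConfigurationError("ensemble member grid mismatch")
        arrs.append(r)
    stack = np.stack(arrs)
    any_nodata = (stack == grid.nodata_value).any(axis=0)
    mean = stack.mean(axis=0)
    mean[any_nodata] = grid.nodata_value
    return mean


@dataclass
class ScenarioGrid:
    """Per-GCM suitability rasters and their ensemble mean for one SSP x
    timeline."""

    ssp: str
    timeline: str
    grid: GridSpec
    per_gcm: Dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, gcm: str, raster: np.ndarray) -> None:
        raster = np.asarray(raster, dtype=float)
        if raster.shape != self.grid.shape:
            raise ConfigurationError("raster shape does not match grid")
        if gcm in self.per_gcm:
            raise ConfigurationError(f"duplicate GCM '{gcm}'")
        self.per_gcm[gcm] = raster

    @property
    def mean(self) -> np.ndarray:
        return ensemble_mean(list(self.per_gcm.values()), self.grid)
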