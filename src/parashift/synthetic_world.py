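"""Synthetic world generator with known ground truth.

Real analyses of this kind start from GBIF occurrence downloads and WorldClim
bioclim rasters. This module stands in for both so the whole pipeline can be
exercised and validated against a *known* niche:

* climate layers are spatially autocorrelated Gaussian random fields
  (white noise smoothed by an isotropic Gaussian kernel, then standardized),
* species suitability is a logistic function of linear/quadratic climate
  terms — and, for the parasite, of the host's suitability,
* presence points are sampled proportional to suitability times an optional
  sampling-bias field (a "hotspot" region is over-sampled by default, which
  is what spatial thinning exists to correct),
* future climates are the current stack plus additive per-layer offsets, one
  :class:`ScenarioShift` per SSP x GCM x timeline.

Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DegenerateInputError
from .grids import ClimateStack, GridSpec, make_grid
from .occurrences import OccurrenceSet

__all__ = [
    "NicheTruth",
    "ScenarioShift",
    "simulate_climate",
    "true_suitability",
    "sample_occurrences",
    "apply_scenario",
    "hotspot_bias",
    "DemoWorld",
    "demo_scenarios",
    "demo_world",
    "SSPS",
    "GCMS",
    "TIMELINES",
]

SSPS = ("SSP126", "SSP245", "SSP370", "SSP585")
GCMS = ("IPSL-CM6A-LR", "MRI-ESM2-0", "CanESM5", "BCC-CSM2-MR")
TIMELINES = ("2041-2060", "2061-2080")


@dataclass(frozen=True)
class NicheTruth:
    """Ground-truth logistic niche.

    suitability = logistic(intercept + sum_k lin[k]*layer_k
                           + sum_k quad[k]*layer_k**2
                           + host_coefficient * host_suitability)

    A host species has ``host_coefficient = 0``; a parasite conditioned on its
    host has ``host_coefficient != 0``.
    """

    intercept: float
    coefficients: Mapping[str, float]
    quadratic: Mapping[str, float] = field(default_factory=dict)
    host_coefficient: float = 0.0


@dataclass(frozen=True)
class ScenarioShift:
    """Additive climate offsets for one SSP x GCM x timeline combination."""

    scenario: str
    gcm: str
    timeline: str
    offsets: Mapping[str, Union[float, np.ndarray]]


def simulate_climate(
    grid: GridSpec,
    layer_names: Sequence[str],
    smoothness: float = 3.0,
    seed: int = 0,
    mask: Optional[np.ndarray] = None,
) -> ClimateStack:
    """Simulate standardized, spatially autocorrelated climate layers.

    Each layer is white Gaussian noise convolved with an isotropic Gaussian
    kernel of standard deviation ``smoothness`` (in cells; 0 = no smoothing),
    then standardized to mean 0 / sd 1 over valid cells.
    """
    layer_names = list(layer_names)
    if not layer_names:
        raise ConfigurationError("at least one layer name is required")
    if smoothness < 0:
        raise ConfigurationError("smoothness must be >= 0")
    rng = np.random.default_rng(seed)
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    layers: Dict[str, np.ndarray] = {}
    for name in layer_names:
        white = rng.standard_normal(grid.shape)
        fld = ndimage.gaussian_filter(white, sigma=smoothness, mode="reflect") \
            if smoothness > 0 else white
        vals = fld[mask]
        sd = vals.std()
        if sd == 0:  # single-cell grid: leave centred value
            fld = fld - vals.mean()
        else:
            fld = (fld - vals.mean()) / sd
        layers[name] = fld
    return ClimateStack(grid=grid, layers=layers, mask=mask)


def _logistic(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def true_suitability(
    stack: ClimateStack,
    truth: NicheTruth,
    host_layer: Optional[str] = None,
) -> np.ndarray:
    """Evaluate the ground-truth niche on a stack -> suitability in [0, 1].

    Invalid cells carry the grid's nodata value.
    """
    for name in list(truth.coefficients) + list(truth.quadratic):
        if name not in stack:
            raise ConfigurationError(f"niche references missing layer '{name}'")
    eta = np.full(stack.grid.shape, float(truth.intercept))
    for name, coef in truth.coefficients.items():
        eta += coef * np.where(stack.mask, stack.layer(name), 0.0)
    for name, coef in truth.quadratic.items():
        eta += coef * np.where(stack.mask, stack.layer(name), 0.0) ** 2
    if truth.host_coefficient != 0.0:
        if host_layer is None or host_layer not in stack:
            raise ConfigurationError(
                "host-conditioned niche requires the host suitability layer"
            )
        eta += truth.host_coefficient * np.where(
            stack.mask, stack.layer(host_layer), 0.0
        )
    suit = _logistic(eta)
    suit[~stack.mask] = stack.grid.nodata_value
    return suit


def sample_occurrences(
    suitability: np.ndarray,
    grid: GridSpec,
    n_points: int,
    seed: int,
    bias: Optional[np.ndarray] = None,
    species: str = "species",
    source: str = "synthetic",
) -> OccurrenceSet:
    """Draw presence points cell-wise with probability ∝ suitability x bias.

    Cells are drawn with replacement; each point is then placed uniformly
    within its cell (not at the center), mimicking presence-only records with
    arbitrary within-cell coordinates.
    """
    if n_points < 1:
        raise ConfigurationError("n_points must be >= 1")
    suit = np.asarray(suitability, dtype=float)
    if suit.shape != grid.shape:
        raise ConfigurationError("suitability shape does not match grid")
    weights = np.where(suit == grid.nodata_value, 0.0, suit)
    weights = np.clip(weights, 0.0, None)
    if bias is not None:
        bias = np.asarray(bias, dtype=float)
        if bias.shape != grid.shape:
            raise ConfigurationError("bias shape does not match grid")
        weights = weights * np.clip(bias, 0.0, None)
    total = weights.sum()
    if total <= 0:
        raise DegenerateInputError("all sampling weights are zero")
    rng = np.random.default_rng(seed)
    flat = weights.ravel() / total
    idx = rng.choice(flat.size, size=n_points, replace=True, p=flat)
    row, col = np.unravel_index(idx, grid.shape)
    lon = grid.lon_min + (col + rng.uniform(0, 1, n_points)) * grid.cell_size
    lat = grid.lat_min + (row + rng.uniform(0, 1, n_points)) * grid.cell_size
    recs = [(species, float(lo), float(la), source) for lo, la in zip(lon, lat)]
    return OccurrenceSet.from_records(recs, stage="raw")


def apply_scenario(stack: ClimateStack, shift: ScenarioShift) -> ClimateStack:
    """Add per-layer offsets on valid cells; grid and mask are unchanged."""
    out = stack.copy()
    for name, offset in shift.offsets.items():
        if name not in stack:
            raise ConfigurationError(f"shift targets missing layer '{name}'")
        if isinstance(offset, np.ndarray):
            if offset.shape != stack.grid.shape:
                raise ConfigurationError(
                    f"offset grid for '{name}' does not match stack grid"
                )
            off = offset
        else:
            off = float(offset)
        layer = out.layers[name]
        layer[out.mask] = layer[out.mask] + (
            off[out.mask] if isinstance(off, np.ndarray) else off
        )
    return out


def hotspot_bias(
    grid: GridSpec,
    lon_range=(5.0, 15.0),
    lat_range=(45.0, 55.0),
    factor: float = 5.0,
) -> np.ndarray:
    """Sampling-bias field: ``factor``-times over-sampling inside a box.

    Emulates the regionally uneven recording effort of citizen-science
    occurrence databases, which spatial thinning is meant to correct.
    """
    lon_c = grid.lon_centers()[None, :]
    lat_c = grid.lat_centers()[:, None]
    box = (
        (lon_c >= lon_range[0]) & (lon_c < lon_range[1])
        & (lat_c >= lat_range[0]) & (lat_c < lat_range[1])
    )
    bias = np.ones(grid.shape)
    bias[np.broadcast_to(box, grid.shape)] = factor
    return bias


# ---------------------------------------------------------------------------
# Bundled demo world
# ---------------------------------------------------------------------------

#: temperature offsets (in sd units of the standardized "bio1" layer) per SSP
#: for the earlier timeline; the later timeline scales them by 1.6. Ordered
#: weakest (sustainability) to strongest (fossil-fuel development).
_SSP_WARMING = {"SSP126": 0.35, "SSP245": 0.55, "SSP370": 0.75, "SSP585": 0.95}
_TIMELINE_FACTOR = {"2041-2060": 1.0, "2061-2080": 1.6}
#: mild inter-GCM spread around the ensemble-mean warming
_GCM_FACTOR = {"IPSL-CM6A-LR": 0.85, "MRI-ESM2-0": 0.95,
               "CanESM5": 1.05, "BCC-CSM2-MR": 1.15}


@dataclass
class DemoWorld:
    """A complete synthetic study system: climate, truths, samples, futures."""

    grid: GridSpec
    stack: ClimateStack
    host_truth: NicheTruth
    parasite_truth: NicheTruth
    host_suitability: np.ndarray
    parasite_suitability: np.ndarray
    host_occurrences: OccurrenceSet
    parasite_occurrences: OccurrenceSet
    bias: np.ndarray
    scenarios: List[ScenarioShift]

    def future_stack(self, shift: ScenarioShift) -> ClimateStack:
        return apply_scenario(self.stack, shift)


def demo_scenarios(
    grid: GridSpec,
    latitude_graded: bool = True,
    temp_layer: str = "bio1",
    precip_layer: str = "bio12",
) -> List[ScenarioShift]:
    """Build the 4 SSP x 4 GCM x 2 timeline shift table for the demo world.

    Warming is additive on the temperature-like layer and, when
    ``latitude_graded``, stronger toward the northern edge (0.7x at the south
    edge to 1.3x at the north), inducing the poleward range movement the
    scenario analysis is designed to detect. A small precipitation offset
    (one tenth of the warming, negative) accompanies each shift.
    """
    lat_norm = (grid.lat_centers() - grid.lat_min) / (grid.lat_max - grid.lat_min)
    grade = (0.7 + 0.6 * lat_norm)[:, None] * np.ones((1, grid.n_cols)) \
        if latitude_graded else np.ones(grid.shape)
    shifts = []
    for ssp in SSPS:
        for timeline in TIMELINES:
            base = _SSP_WARMING[ssp] * _TIMELINE_FACTOR[timeline]
            for gcm in GCMS:
                delta = base * _GCM_FACTOR[gcm]
                shifts.append(
                    ScenarioShift(
                        scenario=ssp,
                        gcm=gcm,
                        timeline=timeline,
                        offsets={
                            temp_layer: delta * grade,
                            precip_layer: -0.1 * delta,
                        },
                    )
                )
    return shifts


def demo_world(
    seed: int = 0,
    extent=(0.0, 40.0, 30.0, 70.0),
    cell_size: float = 0.5,
    n_host: int = 1200,
    n_parasite: int = 900,
    smoothness: float = 4.0,
    latitude_graded_warming: bool = True,
) -> DemoWorld:
    """Generate the bundled demo study system.

    The climate carries a south-to-north temperature gradient ("bio1" =
    latitudinal trend + autocorrelated noise) plus four trend-free layers.
    The host's thermal optimum sits mid-latitude; the parasite is warmer-
    adapted (optimum further south) and strongly host-dependent, so under
    warming both ranges move poleward and the parasite expands.
    """
    grid = make_grid(extent, cell_size)
    rng = np.random.default_rng(seed)
    layer_names = ["bio1", "bio3", "bio8", "bio12", "bio15"]
    stack = simulate_climate(grid, layer_names, smoothness=smoothness,
                             seed=int(rng.integers(2**31 - 1)))
    # overlay the latitudinal temperature trend: warm south, cold north
    lat_norm = (grid.lat_centers() - grid.lat_min) / (grid.lat_max - grid.lat_min)
    trend = 2.5 * (1.0 - 2.0 * lat_norm)[:, None]
    bio1 = 0.6 * stack.layer("bio1") + trend
    stack.layers["bio1"] = np.where(stack.mask, bio1, grid.nodata_value)

    # host: sharp thermal optimum at bio1 = +0.6 (a mid-southern band),
    # moisture-loving; occupies ~10% of the grid
    h_opt, h_curv = 0.6, 8.0
    host_truth = NicheTruth(
        intercept=0.5 - h_curv * h_opt**2,
        coefficients={"bio1": 2 * h_curv * h_opt, "bio12": 2.5},
        quadratic={"bio1": -h_curv},
        host_coefficient=0.0,
    )
    # parasite: warmer optimum (bio1 = +1.2), isothermality signal, strong
    # host dependence; noise layers bio8/bio15 do not enter
    p_opt, p_curv = 1.2, 4.0
    parasite_truth = NicheTruth(
        intercept=-1.5 - p_curv * p_opt**2,
        coefficients={"bio1": 2 * p_curv * p_opt, "bio3": 2.0},
        quadratic={"bio1": -p_curv},
        host_coefficient=4.0,
    )

    host_suit = true_suitability(stack, host_truth)
    work = stack.copy()
    work.add_layer("host_suitability", host_suit)
    parasite_suit = true_suitability(work, parasite_truth,
                                     host_layer="host_suitability")

    bias = hotspot_bias(grid)
    host_occ = sample_occurrences(
        host_suit, grid, n_host, seed=int(rng.integers(2**31 - 1)),
        bias=bias, species="Quercus", source="synthetic",
    )
    parasite_occ = sample_occurrences(
        parasite_suit, grid, n_parasite, seed=int(rng.integers(2**31 - 1)),
        bias=bias, species="Loranthus europaeus", source="synthetic",
    )
    scenarios = demo_scenarios(grid, latitude_graded=latitude_graded_warming)
    return DemoWorld(
        grid=grid,
        stack=stack,
        host_truth=host_truth,
        parasite_truth=parasite_truth,
        host_suitability=host_suit,
        parasite_suitability=parasite_suit,
        host_occurrences=host_occ,
        parasite_occurrences=parasite_occ,
        bias=bias,
        scenarios=scenarios,
    )
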