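"""End-to-end host-conditioned distribution analysis.

The protocol: thin occurrences for both species, fit the host (tree genus)
model on all candidate climate variables, inject the host's predicted
suitability as an extra predictor layer ("host_suitability") for the
parasite, screen the parasite's *climate* predictors for collinearity (the
host layer is always retained), fit and evaluate the parasite model, project
both models under every SSP x GCM x timeline, average suitability across
GCMs within each SSP x timeline, threshold, and classify per-cell range
change.

Every stage draws its seed deterministically from the master seed and the
stage name, so adding stages never perturbs existing ones and a re-run with
the same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError, ParashiftError
from .grids import ClimateStack, GridSpec
from .maxent import (MaxentModel, fit_maxent, percent_contribution,
                     predict_suitability)
from .model_eval import (BinaryRangeMap, EvaluationReport, binarize,
                         max_sens_spec_threshold, range_saturation,
                         split_train_validation)
from .occurrences import (BackgroundSet, OccurrenceSet, clip_to_extent,
                          deduplicate, drop_nodata_points, read_occurrences,
                          sample_background, thin_per_cell, thinning_report)
from .predictor_screen import correlation_matrix, eliminate_collinear
from .projection import HOST_LAYER, ScenarioGrid, project_model
from .range_change import (ChangeSummary, RangeChangeMap, change_report,
                           encode_change, summarize_change)
from .raster_io import read_stack, write_ascii_grid
from . import synthetic_world as sw

__all__ = ["RunConfig", "RunManifest", "stage_seed", "run_host_model",
           "run_parasite_model", "run_all"]

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived by hashing."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything a run needs; round-trips through YAML unchanged."""

    # study frame
    extent: Tuple[float, float, float, float] = (0.0, 40.0, 30.0, 70.0)
    cell_size: float = 0.5
    thin_cell_size: float = 0.25
    n_background: int = 10_000
    split_fraction: float = 0.8
    correlation_threshold: float = 0.7
    screen_protected: List[str] = field(default_factory=list)
    host_mode: str = "reprojected"  # or "static"
    master_seed: int = 0
    host_species: str = "Quercus"
    parasite_species: str = "Loranthus europaeus"
    host_variables: Optional[List[str]] = None  # None = all climate layers
    ssps: List[str] = field(default_factory=lambda: list(sw.SSPS))
    gcms: List[str] = field(default_factory=lambda: list(sw.GCMS))
    timelines: List[str] = field(default_factory=lambda: list(sw.TIMELINES))
    # real inputs (optional); when absent a synthetic world is generated
    host_csv: Optional[str] = None
    parasite_csv: Optional[str] = None
    stack_dir: Optional[str] = None
    scenario_dir: Optional[str] = None
    # synthetic-world parameters
    synthetic_n_host: int = 1200
    synthetic_n_parasite: int = 900
    synthetic_smoothness: float = 4.0
    latitude_graded_warming: bool = True
    output_dir: str = "out"

    def __post_init__(self) -> None:
        if self.host_mode not in ("reprojected", "static"):
            raise ConfigurationError(
                f"host_mode must be 'reprojected' or 'static', "
                f"got '{self.host_mode}'"
            )
        self.extent = tuple(float(v) for v in self.extent)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        d = asdict(self)
        d["extent"] = list(d["extent"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


@dataclass
class RunManifest:
    """Provenance record: parameters, software version, per-file checksums."""

    parameters: Dict
    version: str = __version__
    stages: List[str] = field(default_factory=list)
    checksums: Dict[str, str] = field(default_factory=dict)

    def record_file(self, path: Path, root: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.checksums[str(Path(path).relative_to(root))] = digest

    def save(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump({
                "version": self.version,
                "parameters": self.parameters,
                "stages": self.stages,
                "checksums": self.checksums,
            }, fh, indent=1, sort_keys=True)
        return path


class StageError(ParashiftError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@contextmanager
def _stage(name: str, manifest: Optional[RunManifest] = None):
    logger.info("stage: %s", name)
    try:
        yield
    except ParashiftError as exc:
        raise StageError(name, exc) from exc
    except (OSError, ValueError, KeyError) as exc:
        raise StageError(name, exc) from exc
    if manifest is not None:
        manifest.stages.append(name)


# ---------------------------------------------------------------------------
# input preparation
# ---------------------------------------------------------------------------

@dataclass
class PreparedInputs:
    grid: GridSpec
    stack: ClimateStack
    host_occ: OccurrenceSet
    parasite_occ: OccurrenceSet
    future_stacks: Dict[Tuple[str, str, str], ClimateStack]  # (ssp, timeline, gcm)


def prepare_inputs(config: RunConfig) -> PreparedInputs:
    """Load real inputs when paths are configured, else generate the
    synthetic demo world from the config's study frame."""
    if config.stack_dir is not None:
        stack = read_stack(config.stack_dir)
        grid = stack.grid
        if config.host_csv is None or config.parasite_csv is None:
            raise ConfigurationError("stack_dir given but occurrence CSVs missing")
        host_occ = read_occurrences(config.host_csv)
        parasite_occ = read_occurrences(config.parasite_csv)
        futures: Dict[Tuple[str, str, str], ClimateStack] = {}
        if config.scenario_dir is None:
            raise ConfigurationError("scenario_dir is required with stack_dir")
        scen_root = Path(config.scenario_dir)
        for ssp in config.ssps:
            for timeline in config.timelines:
                for gcm in config.gcms:
                    d = scen_root / ssp / timeline / gcm
                    if not d.exists():
                        raise ConfigurationError(f"missing scenario stack {d}")
                    futures[(ssp, timeline, gcm)] = read_stack(d)
        return PreparedInputs(grid, stack, host_occ, parasite_occ, futures)

    world = sw.demo_world(
        seed=stage_seed(config.master_seed, "world"),
        extent=config.extent,
        cell_size=config.cell_size,
        n_host=config.synthetic_n_host,
        n_parasite=config.synthetic_n_parasite,
        smoothness=config.synthetic_smoothness,
        latitude_graded_warming=config.latitude_graded_warming,
    )
    futures = {}
    for shift in world.scenarios:
        if (shift.scenario in config.ssps and shift.timeline in config.timelines
                and shift.gcm in config.gcms):
            futures[(shift.scenario, shift.timeline, shift.gcm)] = \
                world.future_stack(shift)
    return PreparedInputs(world.grid, world.stack, world.host_occurrences,
                          world.parasite_occurrences, futures)


def _prepare_species_points(
    occ: OccurrenceSet, grid: GridSpec, stack: ClimateStack, config: RunConfig,
    stage: str,
) -> OccurrenceSet:
    occ = deduplicate(occ)
    occ = clip_to_extent(occ, grid)
    occ = thin_per_cell(
        occ, thin_cell_size=config.thin_cell_size,
        seed=stage_seed(config.master_seed, f"thin:{stage}"),
        origin=(grid.lon_min, grid.lat_min),
    )
    return drop_nodata_points(occ, stack)


# ---------------------------------------------------------------------------
# host and parasite models
# ---------------------------------------------------------------------------

@dataclass
class SpeciesModelResult:
    model: MaxentModel
    evaluation: EvaluationReport
    contributions: Dict[str, float]
    current_suitability: np.ndarray
    threshold: float
    current_binary: BinaryRangeMap
    point_saturation: float
    cell_saturation: float
    thinning: Dict
    variables: List[str]


def _fit_and_evaluate(
    occ: OccurrenceSet,
    background: BackgroundSet,
    stack: ClimateStack,
    variables: List[str],
    config: RunConfig,
    stage: str,
) -> SpeciesModelResult:
    raw_count_report = {"after_thinning": len(occ)}
    train, val = split_train_validation(
        occ, fraction=config.split_fraction,
        seed=stage_seed(config.master_seed, f"split:{stage}"),
    )
    Xtr = stack.values_at(*train.coords(), names=variables)
    Xval = stack.values_at(*val.coords(), names=variables)
    Xbg = stack.values_at(*background.coords(), names=variables)
    model = fit_maxent(
        Xtr, Xbg, variables,
        seed=stage_seed(config.master_seed, f"fit:{stage}"),
    )
    val_scores = model.predict(Xval)
    bg_scores = model.predict(Xbg)
    tau, evaluation = max_sens_spec_threshold(val_scores, bg_scores)
    contributions = percent_contribution(
        model, Xtr, Xbg,
        seed=stage_seed(config.master_seed, f"contrib:{stage}"),
    )
    suit = predict_suitability(model, stack)
    brm = binarize(suit, stack.grid, tau, source_model=stage)
    point_sat, cell_sat = range_saturation(occ, brm)
    return SpeciesModelResult(
        model=model, evaluation=evaluation,
        contributions=dict(contributions.contributions),
        current_suitability=suit, threshold=tau, current_binary=brm,
        point_saturation=point_sat, cell_saturation=cell_sat,
        thinning=raw_count_report, variables=variables,
    )


def run_host_model(
    config: RunConfig, inputs: PreparedInputs
) -> Tuple[SpeciesModelResult, Dict[Tuple[str, str, str], np.ndarray]]:
    """Fit the host model and predict host suitability now and (in
    ``reprojected`` mode) under every future scenario stack."""
    occ = _prepare_species_points(
        inputs.host_occ.for_species(config.host_species)
        if config.host_species in inputs.host_occ.species else inputs.host_occ,
        inputs.grid, inputs.stack, config, "host",
    )
    background = sample_background(
        inputs.stack, n=config.n_background,
        seed=stage_seed(config.master_seed, "background:host"),
    )
    variables = config.host_variables or inputs.stack.layer_names
    result = _fit_and_evaluate(occ, background, inputs.stack, list(variables),
                               config, "host")
    host_futures: Dict[Tuple[str, str, str], np.ndarray] = {}
    if config.host_mode == "reprojected":
        for key, fstack in inputs.future_stacks.items():
            host_futures[key] = predict_suitability(result.model, fstack)
    return result, host_futures


@dataclass
class ParasiteResult:
    species_result: SpeciesModelResult
    screened_variables: List[str]
    screen_trace: List
    scenario_grids: Dict[Tuple[str, str], ScenarioGrid]
    change_maps: Dict[Tuple[str, str], RangeChangeMap]
    summaries: Dict[Tuple[str, str], ChangeSummary]


def run_parasite_model(
    config: RunConfig,
    inputs: PreparedInputs,
    host_result: SpeciesModelResult,
    host_futures: Dict[Tuple[str, str, str], np.ndarray],
) -> ParasiteResult:
    """Fit the host-conditioned parasite model, evaluate, project under every
    scenario, ensemble per SSP x timeline, and classify range change."""
    stack = inputs.stack.copy()
    stack.add_layer(HOST_LAYER, host_result.current_suitability)

    occ = _prepare_species_points(
        inputs.parasite_occ.for_species(config.parasite_species)
        if config.parasite_species in inputs.parasite_occ.species
        else inputs.parasite_occ,
        inputs.grid, stack, config, "parasite",
    )
    background = sample_background(
        stack, n=config.n_background,
        seed=stage_seed(config.master_seed, "background:parasite"),
    )
    climate_vars = [n for n in inputs.stack.layer_names]
    report = correlation_matrix(stack, variables=climate_vars,
                                seed=stage_seed(config.master_seed, "screen"))
    retained, trace = eliminate_collinear(
        report, threshold=config.correlation_threshold,
        protected=config.screen_protected,
    )
    variables = retained + [HOST_LAYER]  # host layer exempt from screening
    result = _fit_and_evaluate(occ, background, stack, variables, config,
                               "parasite")

    scenario_grids: Dict[Tuple[str, str], ScenarioGrid] = {}
    change_maps: Dict[Tuple[str, str], RangeChangeMap] = {}
    summaries: Dict[Tuple[str, str], ChangeSummary] = {}
    for ssp in config.ssps:
        for timeline in config.timelines:
            sg = ScenarioGrid(ssp=ssp, timeline=timeline, grid=inputs.grid)
            for gcm in config.gcms:
                key = (ssp, timeline, gcm)
                if key not in inputs.future_stacks:
                    raise ConfigurationError(f"missing future stack {key}")
                host_layer = (
                    host_futures[key] if config.host_mode == "reprojected"
                    else host_result.current_suitability
                )
                suit = project_model(result.model, inputs.future_stacks[key],
                                     host_future=host_layer)
                sg.add(gcm, suit)
            scenario_grids[(ssp, timeline)] = sg
            future_binary = binarize(sg.mean, inputs.grid, result.threshold,
                                     source_model="parasite")
            rcm = encode_change(result.current_binary, future_binary)
            change_maps[(ssp, timeline)] = rcm
            summaries[(ssp, timeline)] = summarize_change(rcm)
    return ParasiteResult(
        species_result=result, screened_variables=retained,
        screen_trace=trace, scenario_grids=scenario_grids,
        change_maps=change_maps, summaries=summaries,
    )


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_all(config: RunConfig, output_dir=None) -> RunManifest:
    """Execute the whole protocol and write models, rasters and reports.

    Outputs land under ``<output_dir>/{models,rasters,reports}``; the
    returned manifest records SHA-256 checksums of every written file.
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    for sub in ("models", "rasters", "reports"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    params = asdict(config)
    params["extent"] = list(params["extent"])
    manifest = RunManifest(parameters=params)

    with _stage("ingest", manifest):
        inputs = prepare_inputs(config)

    with _stage("host_model", manifest):
        host_result, host_futures = run_host_model(config, inputs)
        host_result.model.save(out / "models" / "host.json")
        write_ascii_grid(host_result.current_suitability, inputs.grid,
                         out / "rasters" / "host_current.asc")

    with _stage("parasite_model", manifest):
        parasite = run_parasite_model(config, inputs, host_result, host_futures)
        parasite.species_result.model.save(out / "models" / "parasite.json")
        write_ascii_grid(parasite.species_result.current_suitability,
                         inputs.grid, out / "rasters" / "parasite_current.asc")

    with _stage("ensembles", manifest):
        for (ssp, timeline), sg in parasite.scenario_grids.items():
            write_ascii_grid(sg.mean, inputs.grid,
                             out / "rasters" / f"{ssp}_{timeline}_mean.asc")
        for (ssp, timeline), rcm in parasite.change_maps.items():
            write_ascii_grid(rcm.codes.astype(float), inputs.grid,
                             out / "rasters" / f"{ssp}_{timeline}_change.asc")

    with _stage("reports", manifest):
        report = change_report(parasite.summaries)
        report.to_csv(out / "reports" / "change_report.csv", index=False)
        evaluation = {
            "host": {
                **host_result.evaluation.to_dict(),
                "contributions": host_result.contributions,
                "point_saturation": host_result.point_saturation,
                "cell_saturation": host_result.cell_saturation,
                "variables": host_result.variables,
            },
            "parasite": {
                **parasite.species_result.evaluation.to_dict(),
                "contributions": parasite.species_result.contributions,
                "point_saturation": parasite.species_result.point_saturation,
                "cell_saturation": parasite.species_result.cell_saturation,
                "variables": parasite.species_result.variables,
                "screened_climate_variables": parasite.screened_variables,
                "screen_trace": [
                    {"dropped": d, "pair": list(p), "abs_r": r}
                    for d, p, r in parasite.screen_trace
                ],
            },
        }
        with open(out / "reports" / "evaluation.json", "w") as fh:
            json.dump(evaluation, fh, indent=1)

    for path in sorted(out.rglob("*")):
        if path.is_file():
            manifest.record_file(path, out)
    manifest.save(out / "manifest.json")
    return manifest
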