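"""Collinearity screening of candidate predictor layers.

Bioclimatic variables are strongly inter-correlated; fitting on all of them
inflates variance and muddles variable contributions. The screen computes
pairwise Pearson correlations over jointly valid cells and greedily eliminates
variables until no unprotected pair exceeds ``|r| > threshold`` (0.7 by
default, strict: a pair at exactly 0.7 is kept).

Drop rule: at each step, among variables involved in a violating pair, drop
the one with the largest mean absolute correlation to all currently retained
variables; ties break toward the variable occurring later in the stack's
layer order (the canonical bio1..bio19 ordering). A final restoration pass
re-admits any dropped variable that no longer conflicts (its partners were
dropped later), so the retained set is always maximal. Variables in
``protected`` are never dropped; two collinear protected variables are an
error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, IrreducibleCollinearityError
from .grids import ClimateStack

__all__ = ["CorrelationReport", "correlation_matrix", "eliminate_collinear"]


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations plus the elimination trace."""

    variables: List[str]
    matrix: np.ndarray  # symmetric, unit diagonal; NaN marks undefined entries
    constant_variables: List[str] = field(default_factory=list)
    n_cells: int = 0
    trace: List[Tuple[str, Tuple[str, str], float]] = field(default_factory=list)

    def r(self, a: str, b: str) -> float:
        i, j = self.variables.index(a), self.variables.index(b)
        return float(self.matrix[i, j])

    def to_dict(self) -> Dict:
        return {
            "variables": self.variables,
            "matrix": [[None if np.isnan(v) else float(v) for v in row]
                       for row in self.matrix],
            "constant_variables": self.constant_variables,
            "n_cells": self.n_cells,
            "trace": [
                {"dropped": d, "trigger_pair": list(p), "abs_r": r}
                for d, p, r in self.trace
            ],
        }


def correlation_matrix(
    stack: ClimateStack,
    sample_size: Optional[int] = None,
    seed: int = 0,
    variables: Optional[Sequence[str]] = None,
) -> CorrelationReport:
    """Pearson correlation matrix over jointly valid cells.

    With ``sample_size`` set, a seeded uniform subsample of valid cells is
    used. Constant layers get NaN correlations (flagged, not an error).
    """
    names = list(variables) if variables is not None else stack.layer_names
    if len(names) < 2:
        raise ConfigurationError("need at least two layers to correlate")
    data = stack.valid_matrix(names)
    if data.shape[0] < 3:
        raise ConfigurationError("need at least 3 jointly valid cells")
    if sample_size is not None and sample_size < data.shape[0]:
        rng = np.random.default_rng(seed)
        rows = rng.choice(data.shape[0], size=sample_size, replace=False)
        data = data[rows]
    sd = data.std(axis=0)
    constant = [n for n, s in zip(names, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(data, rowvar=False)
    mat = np.asarray(mat, dtype=float)
    for i, n in enumerate(names):
        if n in constant:
            mat[i, :] = np.nan
            mat[:, i] = np.nan
        mat[i, i] = 1.0
    mat = np.clip(mat, -1.0, 1.0)
    return CorrelationReport(
        variables=names, matrix=mat, constant_variables=constant,
        n_cells=data.shape[0],
    )


def eliminate_collinear(
    report: CorrelationReport,
    threshold: float = 0.7,
    protected: Optional[Sequence[str]] = None,
) -> Tuple[List[str], List[Tuple[str, Tuple[str, str], float]]]:
    """Greedy elimination until all retained pairs satisfy ``|r| <= threshold``.

    Returns the retained variable list (in original order) and the elimination
    trace ``[(dropped, (pair), |r|), ...]``. The trace is also stored on the
    report.
    """
    protected = set(protected or ())
    unknown = protected - set(report.variables)
    if unknown:
        raise ConfigurationError(f"protected variables not in report: {unknown}")
    names = list(report.variables)
    order = {n: i for i, n in enumerate(names)}
    retained = list(names)
    trace: List[Tuple[str, Tuple[str, str], float]] = []

    def absr(a: str, b: str) -> float:
        v = abs(report.r(a, b))
        return -1.0 if np.isnan(v) else v  # undefined pairs never violate

    while True:
        violating = [
            (a, b, absr(a, b))
            for i, a in enumerate(retained)
            for b in retained[i + 1:]
            if absr(a, b) > threshold
        ]
        if not violating:
            break
        prot_pairs = [(a, b, r) for a, b, r in violating
                      if a in protected and b in protected]
        if prot_pairs:
            a, b, r = prot_pairs[0]
            raise IrreducibleCollinearityError(
                f"protected variables '{a}' and '{b}' have |r|={r:.3f} > "
                f"{threshold}"
            )
        candidates = sorted(
            {v for a, b, _ in violating for v in (a, b) if v not in protected}
        )
        # drop the candidate with the largest mean |r| to the retained set;
        # tie -> the later variable in canonical layer order
        def mean_abs_r(v: str) -> float:
            others = [absr(v, o) for o in retained if o != v]
            vals = [x for x in others if x >= 0]
            return float(np.mean(vals)) if vals else 0.0

        scores = [(mean_abs_r(v), order[v], v) for v in candidates]
        _, _, drop = max(scores)
        trigger = max(
            ((a, b, r) for a, b, r in violating if drop in (a, b)),
            key=lambda t: t[2],
        )
        trace.append((drop, (trigger[0], trigger[1]), trigger[2]))
        retained.remove(drop)
    # restoration pass: a variable dropped early may have violated only with
    # variables that were themselves dropped later; add such variables back
    # (in canonical order) so the retained set is maximal
    changed = True
    while changed:
        changed = False
        for name in names:
            if name in retained:
                continue
            if all(absr(name, o) <= threshold for o in retained):
                retained.insert(0, name)
                retained.sort(key=lambda n: order[n])
                trace = [t for t in trace if t[0] != name]
                changed = True
    report.trace = trace
    return retained, trace
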