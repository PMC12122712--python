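"""MaxEnt feature expansion.

Environmental variables are min-max scaled to [0, 1] (scaling fitted on the
training presence + background values only) and expanded into the classic
MaxEnt feature classes:

* linear      — x
* quadratic   — x**2
* product     — x_a * x_b for every unordered variable pair
* hinge       — forward  max(0, (x - k) / (1 - k)) and
                reverse  max(0, (k - x) / k) on an even knot grid

Feature classes are auto-enabled by presence sample size unless given
explicitly: linear + quadratic below 80 presences, plus hinge and product at
80 or more. At prediction time variables may be clamped to the training
[min, max] range so the model never extrapolates features beyond the support
it was fitted on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError

__all__ = ["FeatureSpec", "VariableScaling", "auto_feature_classes",
           "build_features", "expand_features"]

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge")


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature classes to expand, and how."""

    classes: Tuple[str, ...] = ("linear", "quadratic", "product", "hinge")
    hinge_knots: int = 50
    reg_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for c in self.classes:
            if c not in FEATURE_CLASSES:
                raise ConfigurationError(f"unknown feature class '{c}'")
        if self.hinge_knots < 2:
            raise ConfigurationError("hinge_knots must be >= 2")


def auto_feature_classes(n_presence: int) -> Tuple[str, ...]:
    """Default class set by presence count: LQ below 80, LQPH at >= 80."""
    if n_presence < 80:
        return ("linear", "quadratic")
    return ("linear", "quadratic", "product", "hinge")


@dataclass
class VariableScaling:
    """Per-variable min/max fitted on training data; maps values to [0, 1]."""

    variables: List[str]
    mins: np.ndarray
    maxs: np.ndarray
    constant: List[str] = field(default_factory=list)

    @classmethod
    def fit(cls, X: np.ndarray, variables: Sequence[str]) -> "VariableScaling":
        X = np.asarray(X, dtype=float)
        mins = np.nanmin(X, axis=0)
        maxs = np.nanmax(X, axis=0)
        constant = [v for v, lo, hi in zip(variables, mins, maxs) if lo == hi]
        for v in constant:
            logger.warning("variable '%s' is constant over training data; "
                           "excluded from features", v)
        return cls(list(variables), mins, maxs, constant)

    def transform(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if clamp:
            X = np.clip(X, self.mins, self.maxs)
        span = np.where(self.maxs > self.mins, self.maxs - self.mins, 1.0)
        return (X - self.mins) / span

    @property
    def active(self) -> List[int]:
        return [i for i, v in enumerate(self.variables) if v not in self.constant]


def _hinge_knots(n: int) -> Tuple[np.ndarray, np.ndarray]:
    grid = np.linspace(0.0, 1.0, n)
    return grid[:-1], grid[1:]  # forward knots exclude 1, reverse exclude 0


def expand_features(
    X_scaled: np.ndarray,
    variables: Sequence[str],
    active: Sequence[int],
    spec: FeatureSpec,
) -> Tuple[np.ndarray, List[Dict]]:
    """Expand scaled variables into the feature matrix.

    Returns ``(F, meta)`` where ``meta[k]`` describes feature column k:
    ``{"class", "variables", "knot"}``. The expansion is deterministic and
    depends only on the spec, so train and predict paths agree column-wise.
    """
    X_scaled = np.asarray(X_scaled, dtype=float)
    cols: List[np.ndarray] = []
    meta: List[Dict] = []
    fwd_knots, rev_knots = _hinge_knots(spec.hinge_knots)
    for i in active:
        x = X_scaled[:, i]
        v = variables[i]
        if "linear" in spec.classes:
            cols.append(x)
            meta.append({"class": "linear", "variables": [v], "knot": None})
        if "quadratic" in spec.classes:
            cols.append(x**2)
            meta.append({"class": "quadratic", "variables": [v], "knot": None})
        if "hinge" in spec.classes:
            for k in fwd_knots:
                cols.append(np.maximum(0.0, (x - k) / (1.0 - k)))
                meta.append({"class": "hinge", "variables": [v],
                             "knot": float(k)})
            for k in rev_knots:
                cols.append(np.maximum(0.0, (k - x) / k))
                meta.append({"class": "hinge", "variables": [v],
                             "knot": float(-k)})  # sign marks reverse hinges
    if "product" in spec.classes:
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                cols.append(X_scaled[:, i] * X_scaled[:, j])
                meta.append({"class": "product",
                             "variables": [variables[i], variables[j]],
                             "knot": None})
    if not cols:
        raise ConfigurationError("no features could be built "
                                 "(all variables constant?)")
    return np.column_stack(cols), meta


def build_features(
    presence_X: np.ndarray,
    background_X: np.ndarray,
    variables: Sequence[str],
    spec: Optional[FeatureSpec] = None,
) -> Tuple[np.ndarray, np.ndarray, VariableScaling, List[Dict], FeatureSpec]:
    """Fit scaling on training data and expand both presence and background.

    Returns ``(F_presence, F_background, scaling, feature_meta, spec)``; when
    ``spec`` is None the feature classes are auto-selected from the presence
    count.
    """
    presence_X = np.atleast_2d(np.asarray(presence_X, dtype=float))
    background_X = np.atleast_2d(np.asarray(background_X, dtype=float))
    if presence_X.shape[1] != background_X.shape[1]:
        raise ConfigurationError("presence/background variable counts differ")
    if spec is None:
        spec = FeatureSpec(classes=auto_feature_classes(presence_X.shape[0]))
    both = np.vstack([presence_X, background_X])
    scaling = VariableScaling.fit(both, variables)
    active = scaling.active
    if not active:
        raise ConfigurationError("every variable is constant over training data")
    Fp, meta = expand_features(scaling.transform(presence_X), variables,
                               active, spec)
    Fb, _ = expand_features(scaling.transform(background_X), variables,
                            active, spec)
    return Fp, Fb, scaling, meta, spec
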