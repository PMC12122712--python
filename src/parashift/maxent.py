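"""Presence/background maximum-entropy niche model.

The model is the Gibbs density over the training background,

    q_beta(x) = exp(beta . f(x)) / Z,   Z = sum_background exp(beta . f(x_j)),

with features f built by :mod:`parashift.features`. Coefficients minimize the
L1-penalized negative log-likelihood of the presences,

    f(beta) = -mean_presence(beta . f(x)) + log Z(beta)
              + sum_k lambda_k |beta_k|,

solved by FISTA proximal gradient with backtracking and gradient restarts.
This is the standard "maxnet" formulation: an L1-penalized, infinitely
weighted logistic regression of presence against background.

Per-feature penalties are ``lambda_k = multiplier * base * sd_k / sqrt(m)``
with ``m`` the presence count and ``sd_k`` the feature's standard deviation
over presences (floored; see :func:`default_penalties`). The base is
calibrated so that under null data (presences sampled from the background
itself) all coefficients shrink to exactly zero.

Outputs: the *raw* value of a cell is q_beta(x) (sums to one over the
training background); the reported suitability uses the logistic transform
``raw * e^H / (1 + raw * e^H)`` with H the entropy of the fitted background
distribution, which maps typical habitat to ~0.5 and is the scale on which
presence/absence thresholds are usually quoted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .errors import ConfigurationError, ConvergenceError
from .features import (FeatureSpec, VariableScaling, build_features,
                       expand_features)
from .grids import ClimateStack

__all__ = ["MaxentModel", "ContributionTable", "fit_gibbs", "fit_maxent",
           "predict_suitability", "percent_contribution",
           "default_penalties"]

logger = logging.getLogger(__name__)

# Base regularization per feature class. The penalty lambda_k =
# base * sd_k / sqrt(m) is calibrated against the sampling noise of the
# presence constraint: under a null (presences drawn from the background
# distribution) the gradient at beta = 0 fluctuates with standard deviation
# ~ sd_k * sqrt(1/m + 1/n), so a constant base of 4 places the penalty at
# roughly 3-4 null standard deviations for any sample size — a universal-
# threshold style choice under which null data yields the uniform model
# (all coefficients exactly zero) while strong niche signals pass easily.
_REG_BASE = {"linear": 4.0, "quadratic": 4.0, "product": 4.0, "hinge": 4.0}


def default_penalties(
    meta: Sequence[Dict],
    Fp: np.ndarray,
    Fb: np.ndarray,
    multiplier: float = 1.0,
) -> np.ndarray:
    """Per-feature L1 penalties: multiplier * base * sd_k / sqrt(m)."""
    m = Fp.shape[0]
    sd_p = Fp.std(axis=0)
    sd_b = Fb.std(axis=0)
    # sd floor: keeps features that are constant over presences penalized and
    # suppresses sparse-support hinges, whose tiny variance would otherwise
    # let noise buy huge coefficients at negligible penalty
    sd = np.maximum(sd_p, np.maximum(0.05 * sd_b, 0.02))
    base = np.array([_REG_BASE[info["class"]] for info in meta])
    lam = multiplier * base * sd / np.sqrt(m)
    # Boundedness floor. Along beta_k -> +inf the smooth gradient tends to
    # -mean_pres(f_k) + max_bg(f_k); the penalized likelihood is bounded only
    # if lambda_k exceeds that drift (symmetrically for -inf). Features seen
    # at presences but (nearly) absent from the background otherwise run away.
    mp = Fp.mean(axis=0)
    drift = np.maximum(mp - Fb.max(axis=0), Fb.min(axis=0) - mp)
    return np.maximum(lam, 1.1 * np.clip(drift, 0.0, None))


def _kkt_residual(grad: np.ndarray, beta: np.ndarray, lam: np.ndarray) -> float:
    """Max violation of the L1 subgradient optimality conditions."""
    at_zero = beta == 0
    res_zero = np.maximum(np.abs(grad[at_zero]) - lam[at_zero], 0.0)
    res_active = np.abs(grad[~at_zero] + lam[~at_zero] * np.sign(beta[~at_zero]))
    parts = [res_zero, res_active]
    return float(max((p.max() for p in parts if p.size), default=0.0))


def fit_gibbs(
    Fp: np.ndarray,
    Fb: np.ndarray,
    penalties: np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 10_000,
) -> Tuple[np.ndarray, Dict]:
    """Minimize the penalized Gibbs negative log-likelihood by FISTA.

    Returns ``(beta, info)`` with ``info`` carrying iterations and the final
    KKT residual. Raises :class:`ConvergenceError` if the residual is still
    far from stationarity at the iteration cap.
    """
    Fp = np.asarray(Fp, dtype=float)
    Fb = np.asarray(Fb, dtype=float)
    lam = np.asarray(penalties, dtype=float)
    if Fp.shape[1] != Fb.shape[1] or lam.shape[0] != Fp.shape[1]:
        raise ConfigurationError("feature/penalty dimensions disagree")
    mp = Fp.mean(axis=0)

    def smooth(beta: np.ndarray) -> Tuple[float, np.ndarray]:
        eta = Fb @ beta
        lz = logsumexp(eta)
        q = np.exp(eta - lz)
        value = -mp @ beta + lz
        grad = -mp + q @ Fb
        return value, grad

    beta = np.zeros(Fp.shape[1])
    y = beta.copy()
    t = 1.0
    L = 1.0
    f_y, g_y = smooth(y)
    kkt = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # backtracking line search on the smooth part
        while True:
            step = 1.0 / L
            cand = np.sign(y - step * g_y) * np.maximum(
                np.abs(y - step * g_y) - step * lam, 0.0
            )
            d = cand - y
            f_cand, _ = smooth(cand)
            if f_cand <= f_y + g_y @ d + 0.5 * L * (d @ d) + 1e-12:
                break
            L *= 2.0
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y_next = cand + ((t - 1.0) / t_next) * (cand - beta)
        # gradient restart keeps FISTA monotone on this objective
        if (y - cand) @ (cand - beta) > 0:
            y_next = cand
            t_next = 1.0
        beta, y, t = cand, y_next, t_next
        f_y, g_y = smooth(y)
        L = max(L / 1.5, 1e-3)
        if it % 20 == 0 or it == max_iter:
            _, g_beta = smooth(beta)
            kkt = _kkt_residual(g_beta, beta, lam)
            if kkt <= tol:
                break
    else:  # pragma: no cover - loop always breaks or exhausts via range
        pass
    if kkt > tol:
        if kkt > 1e-3:
            raise ConvergenceError(
                f"maxent fit did not converge: KKT residual {kkt:.2e} "
                f"after {it} iterations", gradient_norm=kkt,
            )
        logger.warning("maxent fit stopped at iteration cap with KKT "
                       "residual %.2e", kkt)
    return beta, {"iterations": it, "kkt_residual": kkt}


@dataclass
class MaxentModel:
    """A fitted maximum-entropy niche model."""

    variables: List[str]
    feature_spec: FeatureSpec
    scaling: VariableScaling
    feature_meta: List[Dict]
    beta: np.ndarray
    log_z: float          # log partition over the training background
    entropy: float        # H of the fitted background distribution
    penalties: np.ndarray
    n_presence: int
    n_background: int
    seed: int = 0
    fit_info: Dict = field(default_factory=dict)

    def _features(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        Xs = self.scaling.transform(np.atleast_2d(np.asarray(X, float)),
                                    clamp=clamp)
        F, _ = expand_features(Xs, self.variables, self.scaling.active,
                               self.feature_spec)
        return F

    def predict_raw(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Gibbs density values; sum to 1 over the training background."""
        return np.exp(self._features(X, clamp=clamp) @ self.beta - self.log_z)

    def predict(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Logistic-scale suitability in (0, 1)."""
        raw = self.predict_raw(X, clamp=clamp)
        scaled = raw * np.exp(self.entropy)
        return scaled / (1.0 + scaled)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> Dict:
        return {
            "variables": self.variables,
            "feature_spec": {
                "classes": list(self.feature_spec.classes),
                "hinge_knots": self.feature_spec.hinge_knots,
                "reg_multiplier": self.feature_spec.reg_multiplier,
            },
            "scaling": {
                "variables": self.scaling.variables,
                "mins": self.scaling.mins.tolist(),
                "maxs": self.scaling.maxs.tolist(),
                "constant": self.scaling.constant,
            },
            "feature_meta": self.feature_meta,
            "beta": self.beta.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "penalties": self.penalties.tolist(),
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "seed": self.seed,
            "fit_info": self.fit_info,
        }

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        return path

    @classmethod
    def from_dict(cls, d: Dict) -> "MaxentModel":
        spec = FeatureSpec(
            classes=tuple(d["feature_spec"]["classes"]),
            hinge_knots=d["feature_spec"]["hinge_knots"],
            reg_multiplier=d["feature_spec"]["reg_multiplier"],
        )
        scaling = VariableScaling(
            variables=list(d["scaling"]["variables"]),
            mins=np.asarray(d["scaling"]["mins"], float),
            maxs=np.asarray(d["scaling"]["maxs"], float),
            constant=list(d["scaling"]["constant"]),
        )
        return cls(
            variables=list(d["variables"]),
            feature_spec=spec,
            scaling=scaling,
            feature_meta=list(d["feature_meta"]),
            beta=np.asarray(d["beta"], float),
            log_z=float(d["log_z"]),
            entropy=float(d["entropy"]),
            penalties=np.asarray(d["penalties"], float),
            n_presence=int(d["n_presence"]),
            n_background=int(d["n_background"]),
            seed=int(d.get("seed", 0)),
            fit_info=dict(d.get("fit_info", {})),
        )

    @classmethod
    def load(cls, path) -> "MaxentModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_maxent(
    presence_X: np.ndarray,
    background_X: np.ndarray,
    variables: Sequence[str],
    feature_spec: Optional[FeatureSpec] = None,
    reg_multiplier: float = 1.0,
    penalties: Optional[np.ndarray] = None,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 10_000,
    add_samples_to_background: bool = True,
) -> MaxentModel:
    """Fit the maximum-entropy model on raw variable matrices.

    ``presence_X`` and ``background_X`` are (n, n_variables) arrays of
    environmental values at presence and background locations. Feature
    classes are auto-selected from the presence count unless ``feature_spec``
    is given; ``penalties`` overrides the default per-feature schedule (used
    mainly for cross-checks against reference solvers).

    ``add_samples_to_background`` (on by default, as in the reference MaxEnt
    implementations) includes the presence locations in the set the Gibbs
    density is normalized over during fitting. Without it, any feature-space
    region holding presences but no background points makes the penalized
    likelihood unbounded and coefficients run away. The reported ``raw``
    normalization and entropy are always computed over the background proper.
    """
    presence_X = np.atleast_2d(np.asarray(presence_X, float))
    background_X = np.atleast_2d(np.asarray(background_X, float))
    if presence_X.shape[0] < 10:
        raise ConfigurationError("need at least 10 presences")
    if background_X.shape[0] < presence_X.shape[0]:
        raise ConfigurationError("background must be at least as large as "
                                 "presence set")
    Fp, Fb, scaling, meta, spec = build_features(
        presence_X, background_X, variables, feature_spec
    )
    Fz = np.vstack([Fb, Fp]) if add_samples_to_background else Fb
    if penalties is None:
        penalties = default_penalties(meta, Fp, Fz, multiplier=reg_multiplier)
    else:
        penalties = np.asarray(penalties, dtype=float)
        if penalties.ndim == 0:
            penalties = np.full(Fp.shape[1], float(penalties))
    beta, info = fit_gibbs(Fp, Fz, penalties, tol=tol, max_iter=max_iter)
    eta_b = Fb @ beta
    log_z = float(logsumexp(eta_b))
    q = np.exp(eta_b - log_z)
    entropy = float(-(q * np.log(np.clip(q, 1e-300, None))).sum())
    return MaxentModel(
        variables=list(variables),
        feature_spec=spec,
        scaling=scaling,
        feature_meta=meta,
        beta=beta,
        log_z=log_z,
        entropy=entropy,
        penalties=penalties,
        n_presence=presence_X.shape[0],
        n_background=background_X.shape[0],
        seed=seed,
        fit_info=info,
    )


def predict_suitability(model: MaxentModel, stack: ClimateStack,
                        clamp: bool = True) -> np.ndarray:
    """Predict logistic suitability on every valid cell of a stack.

    Variables are clamped to the training range before feature expansion, so
    cells beyond the fitted support predict as the nearest training boundary.
    Invalid cells carry the grid's nodata value.
    """
    for v in model.variables:
        if v not in stack:
            raise ConfigurationError(f"stack lacks model variable '{v}'")
    X = stack.valid_matrix(model.variables)
    out = np.full(stack.grid.shape, stack.grid.nodata_value, dtype=float)
    out[stack.mask] = model.predict(X, clamp=clamp)
    return out


@dataclass
class ContributionTable:
    """Percent contribution per variable; entries sum to 100."""

    contributions: Dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.contributions.values())
        if abs(total - 100.0) > 0.1:
            raise ConfigurationError(
                f"contributions sum to {total}, expected 100"
            )

    def __getitem__(self, name: str) -> float:
        return self.contributions[name]

    def sorted(self) -> List[Tuple[str, float]]:
        return sorted(self.contributions.items(), key=lambda kv: -kv[1])


def _gain(model: MaxentModel, presence_X, background_X,
          permuted: Optional[Tuple[int, np.ndarray]] = None) -> float:
    """Training gain: mean presence log-density above the uniform background.

    ``permuted`` optionally substitutes one variable column (index, values)
    across the concatenated presence+background rows before evaluation.
    """
    Xp = np.array(presence_X, dtype=float)
    Xb = np.array(background_X, dtype=float)
    if permuted is not None:
        j, col = permuted
        Xp[:, j] = col[: Xp.shape[0]]
        Xb[:, j] = col[Xp.shape[0]:]
    Fp = model._features(Xp)
    Fb = model._features(Xb)
    eta_p = Fp @ model.beta
    eta_b = Fb @ model.beta
    lz = logsumexp(eta_b)
    return float(eta_p.mean() - lz + np.log(Xb.shape[0]))


def percent_contribution(
    model: MaxentModel,
    presence_X: np.ndarray,
    background_X: np.ndarray,
    n_permutations: int = 5,
    seed: int = 0,
) -> ContributionTable:
    """Permutation-importance percent contributions.

    For each variable, its values are permuted jointly across the presence and
    background rows, the drop in training gain is averaged over
    ``n_permutations`` seeded shuffles, negative drops are clipped to zero,
    and drops are normalized to sum to 100. If no variable matters (all drops
    zero) the contribution is spread uniformly.
    """
    presence_X = np.atleast_2d(np.asarray(presence_X, float))
    background_X = np.atleast_2d(np.asarray(background_X, float))
    rng = np.random.default_rng(seed)
    base_gain = _gain(model, presence_X, background_X)
    stacked = np.vstack([presence_X, background_X])
    drops = np.zeros(len(model.variables))
    for j, name in enumerate(model.variables):
        vals = stacked[:, j]
        for _ in range(n_permutations):
            perm = rng.permutation(vals)
            g = _gain(model, presence_X, background_X, permuted=(j, perm))
            drops[j] += base_gain - g
    drops = np.clip(drops / n_permutations, 0.0, None)
    if drops.sum() == 0:
        drops = np.ones_like(drops)
    pct = 100.0 * drops / drops.sum()
    return ContributionTable(dict(zip(model.variables, pct)))
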