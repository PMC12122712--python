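"""Unit tests for the maximum-entropy engine.

The heavier statistical validations (reference-solver agreement on many
designs, null shrinkage at large n, niche recovery over 10 seeds) live in
the acceptance suite; here each behavior is exercised at small scale.
"""

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar

from parashift.errors import ConfigurationError
from parashift.features import FeatureSpec
from parashift.maxent import (MaxentModel, fit_gibbs, fit_maxent,
                              percent_contribution, predict_suitability)


def reference_l1_weighted_logistic(X, y, w, lam_vec):
    """Independent oracle: L1-penalized weighted logistic regression solved
    with scipy L-BFGS-B via the split beta = u - v trick (free intercept,
    penalty on slopes only). Returns the slope vector."""
    n, k = X.shape

    def obj(z):
        alpha, u, v = z[0], z[1:1 + k], z[1 + k:]
        beta = u - v
        t = alpha + X @ beta
        loss = np.where(y == 1, np.logaddexp(0.0, -t), np.logaddexp(0.0, t))
        val = (w * loss).sum() + lam_vec @ (u + v)
        s = 1.0 / (1.0 + np.exp(-t))
        g_t = w * (s - y)
        g_beta = X.T @ g_t
        grad = np.concatenate(([g_t.sum()], g_beta + lam_vec,
                               -g_beta + lam_vec))
        return val, grad

    res = minimize(obj, np.zeros(1 + 2 * k), jac=True, method="L-BFGS-B",
                   bounds=[(None, None)] + [(0, None)] * (2 * k),
                   options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-10})
    return res.x[1:1 + k] - res.x[1 + k:]


def simulate_niche(seed, n_presence=300, n_background=2000, n_var=3):
    rng = np.random.default_rng(seed)
    Xb = rng.standard_normal((n_background, n_var))
    eta = -0.5 + 1.5 * Xb[:, 0] - 1.2 * Xb[:, 1]
    p = 1.0 / (1.0 + np.exp(-eta))
    idx = rng.choice(n_background, size=n_presence, replace=True, p=p / p.sum())
    return Xb[idx], Xb, p


class TestFitGibbs:
    def test_raw_distribution_normalized_over_background(self):
        Xp, Xb, _ = simulate_niche(0)
        model = fit_maxent(Xp, Xb, ["a", "b", "c"])
        np.testing.assert_allclose(model.predict_raw(Xb).sum(), 1.0,
                                   atol=1e-6)

    def test_two_cell_closed_form(self):
        """Single binary feature, all presences at 1, background 50/50: the
        fitted raw ratio between feature=1 and feature=0 matches a direct
        1-D optimization of the same penalized objective."""
        Fp = np.ones((40, 1))
        Fb = np.vstack([np.ones((50, 1)), np.zeros((50, 1))])
        lam = np.array([0.05])

        def objective(b):
            # -mean_pres(b*f) + log sum_bg e^{b*f} + lam|b|
            return -b + np.log(50 * np.exp(b) + 50) + lam[0] * abs(b)

        oracle = minimize_scalar(objective, bounds=(-10, 10), method="bounded",
                                 options={"xatol": 1e-12})
        beta, _ = fit_gibbs(Fp, Fb, lam, tol=1e-9, max_iter=50000)
        assert np.exp(beta[0]) == pytest.approx(np.exp(oracle.x), rel=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_weighted_logistic_reference(self, seed):
        """Infinite-weight correspondence: maxent coefficients equal the L1
        logistic slopes with very large background weights."""
        rng = np.random.default_rng(seed)
        m, n = 40, 300
        Xb = rng.uniform(-2, 2, size=(n, 2))
        eta = 0.8 * Xb[:, 0] - 0.5 * Xb[:, 1]
        p = np.exp(eta)
        Xp = Xb[rng.choice(n, m, p=p / p.sum())]
        spec = FeatureSpec(classes=("linear", "quadratic"))
        model = fit_maxent(Xp, Xb, ["a", "b"], feature_spec=spec,
                           penalties=0.01, add_samples_to_background=False,
                           tol=1e-9, max_iter=50000)
        Fp = model._features(Xp)
        Fb = model._features(Xb)
        X = np.vstack([Fp, Fb])
        y = np.r_[np.ones(m), np.zeros(n)]
        w = np.r_[np.ones(m), np.full(n, 1e8)]
        ref = reference_l1_weighted_logistic(X, y, w, m * model.penalties)
        np.testing.assert_allclose(model.beta, ref, atol=1e-3)

    def test_regularization_monotonicity_in_active_set(self):
        Xp, Xb, _ = simulate_niche(4)
        counts = []
        for mult in (0.5, 1.0, 2.0, 4.0):
            model = fit_maxent(Xp, Xb, ["a", "b", "c"], reg_multiplier=mult)
            counts.append(int((model.beta != 0).sum()))
        assert counts == sorted(counts, reverse=True)

    def test_too_few_presences_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ConfigurationError):
            fit_maxent(rng.uniform(0, 1, (5, 2)), rng.uniform(0, 1, (50, 2)),
                       ["a", "b"])


class TestPredict:
    def test_prediction_bit_reproducible(self):
        Xp, Xb, _ = simulate_niche(1)
        model = fit_maxent(Xp, Xb, ["a", "b", "c"])
        np.testing.assert_array_equal(model.predict(Xb[:10]),
                                      model.predict(Xb[:10]))

    def test_clamped_cell_predicts_as_boundary(self):
        Xp, Xb, _ = simulate_niche(2)
        model = fit_maxent(Xp, Xb, ["a", "b", "c"])
        hi = np.vstack([Xp, Xb]).max(axis=0)
        beyond = hi + 5.0
        np.testing.assert_allclose(model.predict(beyond[None, :]),
                                   model.predict(hi[None, :]), rtol=1e-12)

    def test_suitability_raster_propagates_nodata(self, masked_stack):
        rng = np.random.default_rng(3)
        Xb = masked_stack.valid_matrix()
        Xp = Xb[rng.choice(len(Xb), 30)]
        spec = FeatureSpec(classes=("linear", "quadratic"))
        model = fit_maxent(Xp, Xb, masked_stack.layer_names, feature_spec=spec)
        suit = predict_suitability(model, masked_stack)
        assert suit[0, 0] == masked_stack.grid.nodata_value
        vals = suit[masked_stack.mask]
        assert np.all((vals > 0) & (vals < 1))

    def test_missing_variable_is_configuration_error(self, masked_stack):
        Xp, Xb, _ = simulate_niche(5, n_var=3)
        model = fit_maxent(Xp, Xb, ["a", "b", "c"])
        with pytest.raises(ConfigurationError):
            predict_suitability(model, masked_stack)

    def test_serialization_roundtrip_preserves_predictions(self, tmp_path):
        Xp, Xb, _ = simulate_niche(6)
        model = fit_maxent(Xp, Xb, ["a", "b", "c"])
        path = model.save(tmp_path / "m.json")
        back = MaxentModel.load(path)
        np.testing.assert_allclose(back.predict(Xb[:20]), model.predict(Xb[:20]),
                                   rtol=1e-12)


class TestPercentContribution:
    def test_single_variable_gets_everything(self):
        rng = np.random.default_rng(7)
        Xb = rng.standard_normal((1000, 1))
        eta = 1.5 * Xb[:, 0]
        p = np.exp(eta)
        Xp = Xb[rng.choice(1000, 200, p=p / p.sum())]
        model = fit_maxent(Xp, Xb, ["x"])
        table = percent_contribution(model, Xp, Xb, seed=0)
        assert table["x"] == pytest.approx(100.0, abs=1e-9)

    def test_shares_sum_to_100(self):
        Xp, Xb, _ = simulate_niche(8)
        model = fit_maxent(Xp, Xb, ["a", "b", "c"])
        table = percent_contribution(model, Xp, Xb, seed=1)
        assert sum(table.contributions.values()) == pytest.approx(100.0,
                                                                  abs=0.1)

    def test_irrelevant_variable_contributes_little(self):
        """A variable with true coefficient 0 stays below 10% over seeds."""
        for seed in range(4):
            rng = np.random.default_rng(200 + seed)
            Xb = rng.standard_normal((1000, 3))
            eta = -0.5 + 1.5 * Xb[:, 0] - 1.2 * Xb[:, 1]  # column 2 inert
            p = 1.0 / (1.0 + np.exp(-eta))
            Xp = Xb[rng.choice(1000, 300, replace=True, p=p / p.sum())]
            model = fit_maxent(Xp, Xb, ["a", "b", "noise"])
            table = percent_contribution(model, Xp, Xb, seed=seed)
            assert table["noise"] < 10.0
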