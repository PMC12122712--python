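import numpy as np
import pytest

from parashift.errors import ConfigurationError, DegenerateInputError
from parashift.grids import ClimateStack, make_grid
from parashift.synthetic_world import (NicheTruth, ScenarioShift,
                                       apply_scenario, demo_world,
                                       hotspot_bias, sample_occurrences,
                                       simulate_climate, true_suitability)


def lag1_neighbor_correlation(field):
    """Moran-style correlation between horizontally adjacent cells,
    computed by direct pairing."""
    a = field[:, :-1].ravel()
    b = field[:, 1:].ravel()
    return np.corrcoef(a, b)[0, 1]


class TestSimulateClimate:
    def test_standardization(self):
        grid = make_grid((0, 0, 10, 10), 1.0)
        stack = simulate_climate(grid, ["a"], smoothness=0.0, seed=3)
        vals = stack.layer("a")[stack.mask]
        assert 0.9 <= vals.std() <= 1.1
        assert abs(vals.mean()) < 1e-12

    def test_determinism(self):
        grid = make_grid((0, 0, 20, 20), 1.0)
        s1 = simulate_climate(grid, ["a", "b"], smoothness=2.0, seed=11)
        s2 = simulate_climate(grid, ["a", "b"], smoothness=2.0, seed=11)
        for name in ("a", "b"):
            np.testing.assert_array_equal(s1.layer(name), s2.layer(name))

    def test_smoothing_increases_spatial_autocorrelation(self):
        grid = make_grid((0, 0, 30, 30), 1.0)
        wins = 0
        for seed in range(20):
            rough = simulate_climate(grid, ["x"], smoothness=0.0, seed=seed)
            smooth = simulate_climate(grid, ["x"], smoothness=5.0, seed=seed)
            if (lag1_neighbor_correlation(smooth.layer("x"))
                    > lag1_neighbor_correlation(rough.layer("x"))):
                wins += 1
        assert wins == 20

    def test_empty_layer_list_rejected(self):
        grid = make_grid((0, 0, 5, 5), 1.0)
        with pytest.raises(ConfigurationError):
            simulate_climate(grid, [], seed=0)

    def test_mask_conservation(self):
        grid = make_grid((0, 0, 10, 10), 1.0)
        mask = np.ones(grid.shape, dtype=bool)
        mask[2, 3] = False
        stack = simulate_climate(grid, ["a"], smoothness=1.0, seed=5, mask=mask)
        assert stack.layer("a")[2, 3] == grid.nodata_value
        np.testing.assert_array_equal(stack.mask, mask)


class TestTrueSuitability:
    def test_zero_model_gives_half(self, masked_stack):
        truth = NicheTruth(intercept=0.0, coefficients={})
        suit = true_suitability(masked_stack, truth)
        assert np.all(suit[masked_stack.mask] == 0.5)
        assert suit[0, 0] == masked_stack.grid.nodata_value

    def test_logistic_of_known_value(self, small_grid):
        stack = ClimateStack(grid=small_grid,
                             layers={"t": np.full(small_grid.shape, 2.0)})
        truth = NicheTruth(intercept=0.0, coefficients={"t": 1.0})
        suit = true_suitability(stack, truth)
        # logistic(2) = 1 / (1 + e^-2)
        np.testing.assert_allclose(suit, 1.0 / (1.0 + np.exp(-2.0)),
                                   rtol=1e-12)

    def test_large_intercept_saturates_monotonically(self, masked_stack):
        prev = None
        for b0 in (0.0, 5.0, 20.0):
            suit = true_suitability(
                masked_stack, NicheTruth(intercept=b0, coefficients={}))
            v = suit[masked_stack.mask]
            if prev is not None:
                assert np.all(v >= prev)
            prev = v
        assert np.all(prev > 1.0 - 1e-8)

    def test_missing_layer_rejected(self, masked_stack):
        truth = NicheTruth(intercept=0.0, coefficients={"nope": 1.0})
        with pytest.raises(ConfigurationError):
            true_suitability(masked_stack, truth)

    def test_host_layer_required_when_host_dependent(self, masked_stack):
        truth = NicheTruth(intercept=0.0, coefficients={},
                           host_coefficient=2.0)
        with pytest.raises(ConfigurationError):
            true_suitability(masked_stack, truth)


class TestSampleOccurrences:
    def test_degenerate_support(self, small_grid):
        suit = np.zeros(small_grid.shape)
        suit[4, 7] = 1.0
        occ = sample_occurrences(suit, small_grid, 25, seed=0)
        row, col = small_grid.cell_index(*occ.coords())
        assert np.all(row == 4) and np.all(col == 7)

    def test_all_zero_weights_rejected(self, small_grid):
        with pytest.raises(DegenerateInputError):
            sample_occurrences(np.zeros(small_grid.shape), small_grid, 5, seed=0)

    def test_bias_shifts_sampling_by_binomial_margin(self):
        grid = make_grid((0, 0, 20, 10), 1.0)
        suit = np.ones(grid.shape)
        bias = np.ones(grid.shape)
        bias[:, :10] = 10.0  # left half over-sampled 10x
        n = 10_000
        occ = sample_occurrences(suit, grid, n, seed=123, bias=bias)
        lon, _ = occ.coords()
        left = (lon < 10.0).sum()
        p = 10.0 / 11.0
        sd = np.sqrt(n * p * (1 - p))
        assert abs(left - n * p) <= 3 * sd

    def test_determinism(self, small_grid):
        suit = np.full(small_grid.shape, 0.5)
        a = sample_occurrences(suit, small_grid, 50, seed=9)
        b = sample_occurrences(suit, small_grid, 50, seed=9)
        assert a.table.equals(b.table)


class TestApplyScenario:
    def test_zero_shift_is_identity(self, masked_stack):
        out = apply_scenario(masked_stack, ScenarioShift(
            "SSP126", "GCM1", "2041-2060", offsets={}))
        for name in masked_stack.layer_names:
            np.testing.assert_array_equal(out.layer(name),
                                          masked_stack.layer(name))

    def test_scalar_shift_only_touches_target_layer(self, masked_stack):
        out = apply_scenario(masked_stack, ScenarioShift(
            "SSP126", "GCM1", "2041-2060", offsets={"bio1": 1.0}))
        m = masked_stack.mask
        np.testing.assert_allclose(out.layer("bio1")[m],
                                   masked_stack.layer("bio1")[m] + 1.0)
        np.testing.assert_array_equal(out.layer("bio12"),
                                      masked_stack.layer("bio12"))
        # masked cells untouched
        assert out.layer("bio1")[0, 0] == masked_stack.grid.nodata_value

    def test_shift_composition_is_additive(self, masked_stack):
        sa = ScenarioShift("S", "G", "T", offsets={"bio1": 0.7})
        sb = ScenarioShift("S", "G", "T", offsets={"bio1": 0.5})
        sab = ScenarioShift("S", "G", "T", offsets={"bio1": 1.2})
        two = apply_scenario(apply_scenario(masked_stack, sa), sb)
        one = apply_scenario(masked_stack, sab)
        np.testing.assert_allclose(two.layer("bio1"), one.layer("bio1"),
                                   rtol=1e-12)

    def test_unknown_layer_rejected(self, masked_stack):
        with pytest.raises(ConfigurationError):
            apply_scenario(masked_stack, ScenarioShift(
                "S", "G", "T", offsets={"bio99": 1.0}))


class TestDemoWorld:
    def test_world_is_deterministic_and_complete(self):
        w1 = demo_world(seed=5, extent=(0, 40, 10, 50), cell_size=1.0,
                        n_host=60, n_parasite=40)
        w2 = demo_world(seed=5, extent=(0, 40, 10, 50), cell_size=1.0,
                        n_host=60, n_parasite=40)
        assert w1.host_occurrences.table.equals(w2.host_occurrences.table)
        np.testing.assert_array_equal(w1.parasite_suitability,
                                      w2.parasite_suitability)
        # 4 SSPs x 2 timelines x 4 GCMs
        assert len(w1.scenarios) == 32

    def test_host_suitability_in_unit_interval(self):
        w = demo_world(seed=1, extent=(0, 40, 10, 50), cell_size=1.0,
                       n_host=60, n_parasite=40)
        v = w.host_suitability[w.stack.mask]
        assert np.all((v >= 0) & (v <= 1))

    def test_bias_hotspot_is_region_limited(self, small_grid):
        bias = hotspot_bias(small_grid, lon_range=(2, 5), lat_range=(42, 45),
                            factor=5.0)
        assert bias[small_grid.cell_index(3.0, 43.0)] == 5.0
        assert bias[small_grid.cell_index(8.0, 48.0)] == 1.0
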