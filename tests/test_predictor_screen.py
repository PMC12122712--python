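import itertools

import numpy as np
import pytest

from parashift.errors import IrreducibleCollinearityError
from parashift.grids import ClimateStack, make_grid
from parashift.predictor_screen import (CorrelationReport, correlation_matrix,
                                        eliminate_collinear)


def stack_from_columns(cols):
    """Build a stack whose layers are reshaped columns of a matrix."""
    n = next(iter(cols.values())).size
    side = int(np.sqrt(n))
    grid = make_grid((0, 0, side, side), 1.0)
    return ClimateStack(grid=grid,
                        layers={k: np.asarray(v).reshape(side, side)
                                for k, v in cols.items()})


def brute_force_pearson(x, y):
    """Two-pass covariance Pearson r, by explicit loops."""
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    sxy = sxx = syy = 0.0
    for xi, yi in zip(x, y):
        sxy += (xi - mx) * (yi - my)
        sxx += (xi - mx) ** 2
        syy += (yi - my) ** 2
    return sxy / np.sqrt(sxx * syy)


def naive_greedy(names, mat, threshold, protected=()):
    """Independent re-implementation of the drop rule (plus restoration
    pass) with plain loops."""
    retained = list(names)
    order = {n: i for i, n in enumerate(names)}

    def absr(a, b):
        v = abs(mat[order[a], order[b]])
        return -1.0 if np.isnan(v) else v

    while True:
        pairs = [(a, b) for i, a in enumerate(retained)
                 for b in retained[i + 1:] if absr(a, b) > threshold]
        if not pairs:
            break
        cands = sorted({v for p in pairs for v in p if v not in protected})
        best, best_key = None, None
        for v in cands:
            vals = [absr(v, o) for o in retained if o != v and absr(v, o) >= 0]
            key = (float(np.mean(vals)), order[v])
            if best_key is None or key > best_key:
                best, best_key = v, key
        retained.remove(best)
    changed = True
    while changed:
        changed = False
        for n in names:
            if n not in retained and all(absr(n, o) <= threshold
                                         for o in retained):
                retained.append(n)
                retained.sort(key=order.get)
                changed = True
    return retained


class TestCorrelationMatrix:
    def test_affine_relation_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(64)
        stack = stack_from_columns({"A": a, "B": 2 * a + 3, "C": -a})
        rep = correlation_matrix(stack)
        assert rep.r("A", "B") == pytest.approx(1.0, abs=1e-12)
        assert rep.r("A", "C") == pytest.approx(-1.0, abs=1e-12)

    def test_matches_two_pass_covariance_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(100)
        b = rng.standard_normal(100)
        stack = stack_from_columns({"A": a, "B": b})
        rep = correlation_matrix(stack)
        assert rep.r("A", "B") == pytest.approx(
            brute_force_pearson(list(a), list(b)), abs=1e-12)

    def test_constant_layer_flagged_with_nan(self):
        rng = np.random.default_rng(1)
        stack = stack_from_columns({"A": rng.standard_normal(25),
                                    "K": np.full(25, 7.0)})
        rep = correlation_matrix(stack)
        assert rep.constant_variables == ["K"]
        assert np.isnan(rep.r("A", "K"))
        assert rep.r("K", "K") == 1.0

    def test_subsample_is_seeded(self, masked_stack):
        r1 = correlation_matrix(masked_stack, sample_size=50, seed=5)
        r2 = correlation_matrix(masked_stack, sample_size=50, seed=5)
        np.testing.assert_array_equal(r1.matrix, r2.matrix)

    def test_symmetric_unit_diagonal(self, masked_stack):
        rep = correlation_matrix(masked_stack)
        np.testing.assert_allclose(rep.matrix, rep.matrix.T)
        np.testing.assert_allclose(np.diag(rep.matrix), 1.0)


class TestEliminateCollinear:
    def make_report(self, names, mat):
        return CorrelationReport(variables=list(names),
                                 matrix=np.asarray(mat, float))

    def test_exact_threshold_pair_retained(self):
        rep = self.make_report("AB", [[1.0, 0.7], [0.7, 1.0]])
        retained, trace = eliminate_collinear(rep, threshold=0.7)
        assert retained == ["A", "B"] and trace == []

    def test_three_identical_layers_leave_one(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(49)
        stack = stack_from_columns({"A": a, "B": a.copy(), "C": a.copy()})
        rep = correlation_matrix(stack)
        retained, _ = eliminate_collinear(rep, threshold=0.7)
        assert len(retained) == 1

    def test_protected_variables_never_dropped(self):
        rep = self.make_report("AB", [[1.0, 0.95], [0.95, 1.0]])
        retained, _ = eliminate_collinear(rep, 0.7, protected=["B"])
        assert retained == ["B"]

    def test_two_collinear_protected_is_an_error(self):
        rep = self.make_report("AB", [[1.0, 0.95], [0.95, 1.0]])
        with pytest.raises(IrreducibleCollinearityError):
            eliminate_collinear(rep, 0.7, protected=["A", "B"])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_greedy_and_is_maximal(self, seed):
        """On random 6-layer instances the retained set equals an independent
        re-implementation of the drop rule, satisfies the pairwise bound, and
        is maximal (verified by enumerating all supersets)."""
        rng = np.random.default_rng(seed)
        base = rng.standard_normal((200, 3))
        mix = rng.uniform(-1, 1, size=(3, 6))
        data = base @ mix + 0.35 * rng.standard_normal((200, 6))
        names = [f"v{i}" for i in range(6)]
        mat = np.corrcoef(data, rowvar=False)
        rep = self.make_report(names, mat)
        retained, _ = eliminate_collinear(rep, threshold=0.7)
        assert retained == naive_greedy(names, mat, 0.7)
        idx = {n: i for i, n in enumerate(names)}
        kept = [idx[n] for n in retained]
        assert all(abs(mat[i, j]) <= 0.7 for i, j in
                   itertools.combinations(kept, 2))
        # maximality: no dropped variable can be added back
        for n in set(names) - set(retained):
            assert any(abs(mat[idx[n], k]) > 0.7 for k in kept)

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_monotonicity(self, seed):
        """Raising the threshold never shrinks the retained set size."""
        rng = np.random.default_rng(100 + seed)
        base = rng.standard_normal((150, 2))
        mix = rng.uniform(-1, 1, size=(2, 5))
        data = base @ mix + 0.3 * rng.standard_normal((150, 5))
        mat = np.corrcoef(data, rowvar=False)
        rep_sizes = []
        for thr in (0.5, 0.7, 0.9):
            rep = self.make_report([f"v{i}" for i in range(5)], mat)
            retained, _ = eliminate_collinear(rep, threshold=thr)
            rep_sizes.append(len(retained))
        assert rep_sizes == sorted(rep_sizes)

    def test_trace_replays_to_same_set(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal((150, 2))
        data = base @ rng.uniform(-1, 1, (2, 5)) \
            + 0.2 * rng.standard_normal((150, 5))
        names = [f"v{i}" for i in range(5)]
        mat = np.corrcoef(data, rowvar=False)
        rep = self.make_report(names, mat)
        retained, trace = eliminate_collinear(rep, 0.7)
        replayed = [n for n in names if n not in {d for d, _, _ in trace}]
        assert replayed == retained
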