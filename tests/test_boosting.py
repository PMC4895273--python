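"""Unit and property tests of the boosting learner and its primitives."""

import json

import numpy as np
import pytest

from rsaboost.boosting import (
    GradientBoostedRSA,
    LossFunction,
    RegressionTree,
    TrainConfig,
    fit_tree,
    huber_delta,
    huber_loss,
    initial_value,
    leaf_updates,
    pseudo_residuals,
)

HUBER = LossFunction("huber")
SQUARED = LossFunction("squared")


def grid_minimize_constant(y, delta, grid=None):
    """Independent oracle: 1-D grid minimization of the total Huber loss over
    a constant; returns the midpoint of the (near-)minimal grid points."""
    if grid is None:
        grid = np.arange(-1.0, 1.0 + 1e-9, 1e-4)
    losses = np.array([huber_loss(y, np.full(len(y), b), delta) for b in grid])
    near = grid[losses <= losses.min() + 1e-12]
    return 0.5 * (near[0] + near[-1])


def single_leaf_tree(n):
    return RegressionTree(
        feature=np.array([-1]),
        threshold=np.array([np.nan]),
        children_left=np.array([-1]),
        children_right=np.array([-1]),
        value=np.array([0.0]),
        n_samples=np.array([n]),
        split_gain=np.array([0.0]),
    )


# -------------------------------------------------------------------------
# primitives
# -------------------------------------------------------------------------

class TestInitialValue:
    @pytest.mark.parametrize("loss", [HUBER, SQUARED])
    def test_constant_vector(self, loss):
        assert initial_value([0.4, 0.4, 0.4], loss) == pytest.approx(0.4)

    def test_squared_is_mean(self):
        assert initial_value([0.0, 1.0], SQUARED) == 0.5

    def test_huber_matches_small_delta_grid_minimizer(self):
        y = np.array([0.0, 0.1, 0.9])
        est = initial_value(y, HUBER)
        oracle = grid_minimize_constant(y, delta=0.01, grid=np.arange(0, 1, 1e-4))
        assert est == pytest.approx(0.1)
        assert est == pytest.approx(oracle, abs=1e-3)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            initial_value([], HUBER)


class TestPseudoResiduals:
    def test_huber_inside_and_outside_transition(self):
        y = np.array([0.3, -0.9])
        f = np.zeros(2)
        out = pseudo_residuals(y, f, HUBER, delta=0.5)
        assert out[0] == pytest.approx(0.3)   # |r| <= delta: raw residual
        assert out[1] == pytest.approx(-0.5)  # |r| > delta: delta * sign

    def test_squared_is_plain_residual(self):
        out = pseudo_residuals([0.3], [0.0], SQUARED)
        assert out[0] == pytest.approx(0.3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            pseudo_residuals([1.0, 2.0], [1.0], SQUARED)


class TestHuberDelta:
    def test_alpha_one_is_max_abs(self):
        assert huber_delta([0.1, -0.2, 0.3, -0.4], 1.0) == pytest.approx(0.4)

    def test_degenerate_residuals_floor(self):
        assert huber_delta(np.zeros(5), 0.9) == pytest.approx(1e-12)

    def test_median_quantile_convention(self):
        # linear-interpolation convention: sorted |r| = [1,2,3,4] -> 2.5
        assert huber_delta([-1, 2, -3, 4], 0.5) == pytest.approx(2.5)

    def test_matches_sorted_interpolation_oracle(self, rng):
        r = rng.normal(size=31)
        for alpha in (0.5, 0.9, 1.0):
            assert huber_delta(r, alpha) == pytest.approx(
                np.quantile(np.abs(r), alpha), abs=1e-12
            )


# -------------------------------------------------------------------------
# tree fitting
# -------------------------------------------------------------------------

def brute_force_stump(X, t):
    """Exhaustive scan over every feature and midpoint (loop reference)."""
    best = (np.inf, None, None)
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (a + b)
            left = X[:, j] <= thr
            sl = t[left] - t[left].mean()
            sr = t[~left] - t[~left].mean()
            sse = float(sl @ sl + sr @ sr)
            if sse < best[0] - 1e-12:
                best = (sse, j, thr)
    return best


class TestFitTree:
    CFG = TrainConfig(max_depth=2, min_samples_leaf=1)

    def test_single_sample_is_leaf(self):
        tree = fit_tree(np.array([[1.0]]), np.array([0.7]), self.CFG)
        assert tree.n_leaves == 1
        assert tree.predict(np.array([[5.0]]))[0] == pytest.approx(0.7)

    def test_separable_pair_splits_at_midpoint(self):
        tree = fit_tree(np.array([[0.0], [1.0]]), np.array([0.0, 1.0]), self.CFG)
        assert tree.n_leaves == 2
        assert tree.threshold[0] == pytest.approx(0.5)
        pred = tree.predict(np.array([[0.0], [1.0]]))
        assert np.allclose(pred, [0.0, 1.0])  # training SSE = 0

    def test_constant_targets_single_leaf(self):
        X = np.arange(6, dtype=float).reshape(-1, 1)
        tree = fit_tree(X, np.full(6, 0.3), self.CFG)
        assert tree.n_leaves == 1

    def test_depth2_matches_loop_reference(self, rng):
        """Vectorized depth-2 fits on 8-point 1-feature data equal an
        independently coded loop reference that brute-forces every split
        point at each greedy step (same structure and training SSE)."""

        def greedy_reference(X, t, depth):
            sse, j, thr = brute_force_stump(X, t)
            if j is None or depth == 0 or np.ptp(t) == 0:
                return [], np.full(len(t), t.mean())
            left = X[:, 0] <= thr
            parent = float(((t - t.mean()) ** 2).sum())
            if parent - sse <= 0:
                return [], np.full(len(t), t.mean())
            lt, lp = greedy_reference(X[left], t[left], depth - 1)
            rt, rp = greedy_reference(X[~left], t[~left], depth - 1)
            pred = np.empty(len(t))
            pred[left], pred[~left] = lp, rp
            return [thr] + lt + rt, pred

        for _ in range(10):
            X = rng.uniform(size=(8, 1))
            t = rng.uniform(size=8)
            tree = fit_tree(X, t, self.CFG)
            ref_thresholds, ref_pred = greedy_reference(X, t, 2)
            got_thresholds = tree.threshold[tree.feature >= 0]
            assert sorted(got_thresholds) == pytest.approx(
                sorted(ref_thresholds), abs=1e-12
            )
            assert np.abs(tree.predict(X) - ref_pred).max() < 1e-12

    def test_respects_min_samples_leaf(self, rng):
        X = rng.uniform(size=(30, 3))
        t = rng.uniform(size=30)
        tree = fit_tree(X, t, TrainConfig(max_depth=6, min_samples_leaf=5))
        leaves = tree.leaf_node_ids()
        assert (tree.n_samples[leaves] >= 5).all()

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            fit_tree(np.empty((0, 2)), np.empty(0), self.CFG)


class TestLeafUpdates:
    def test_squared_is_mean_residual(self):
        tree = single_leaf_tree(2)
        _, upd = leaf_updates(
            tree, np.array([0.5, 0.5]), np.array([0.3, 0.3]), SQUARED,
            leaf_of_sample=np.zeros(2, dtype=int),
        )
        assert upd[0] == pytest.approx(0.2)

    def test_single_sample_huber_is_residual(self):
        tree = single_leaf_tree(1)
        _, upd = leaf_updates(
            tree, np.array([0.9]), np.array([0.2]), HUBER, delta=0.05,
            leaf_of_sample=np.zeros(1, dtype=int),
        )
        assert upd[0] == pytest.approx(0.7)

    def test_huber_update_matches_grid_minimizer(self):
        r = np.array([0.0, 0.1, 0.9])
        tree = single_leaf_tree(3)
        _, upd = leaf_updates(
            tree, r, np.zeros(3), HUBER, delta=0.2,
            leaf_of_sample=np.zeros(3, dtype=int),
        )
        oracle = grid_minimize_constant(r, delta=0.2)
        assert upd[0] == pytest.approx(oracle, abs=1e-3)
        assert upd[0] == pytest.approx(0.15, abs=1e-6)  # analytic root

    def test_huber_update_random_leaves(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 15))
            r = rng.uniform(-0.6, 0.6, size=n)
            delta = float(rng.uniform(0.05, 0.5))
            tree = single_leaf_tree(n)
            _, upd = leaf_updates(
                tree, r, np.zeros(n), HUBER, delta=delta,
                leaf_of_sample=np.zeros(n, dtype=int),
            )
            assert upd[0] == pytest.approx(
                grid_minimize_constant(r, delta), abs=1e-3
            )


# -------------------------------------------------------------------------
# the boosting loop
# -------------------------------------------------------------------------

def naive_stump_boost(X, y, n_stages, nu):
    """Independent reference: unoptimized loop of stump boosting with
    squared loss (mean init, exhaustive stump scan, mean leaf updates)."""
    preds = []
    F = np.full(len(y), y.mean())
    for _ in range(n_stages):
        r = y - F
        _, j, thr = brute_force_stump(X, r)
        if j is None:
            preds.append(F.copy())
            continue
        left = X[:, j] <= thr
        F = F + nu * np.where(left, r[left].mean(), r[~left].mean())
        preds.append(F.copy())
    return preds


class TestBoosting:
    def test_zero_stages_predicts_f0(self):
        X = np.zeros((4, 2))
        y = np.array([0.3, 0.3, 0.3, 0.3])
        m = GradientBoostedRSA(n_stages=0).fit(X, y)
        assert np.allclose(m.predict(X), 0.3)

    def test_constant_targets_stay_constant(self, rng):
        X = rng.uniform(size=(20, 3))
        y = np.full(20, 0.6)
        m = GradientBoostedRSA(n_stages=5).fit(X, y)
        assert np.allclose(m.predict(X), 0.6, atol=1e-9)

    def test_matches_naive_reference_staged(self, rng):
        """Squared loss, nu=1, depth-1 trees: staged predictions equal an
        independently coded stump-boosting loop to 1e-10."""
        X = rng.uniform(size=(10, 2))
        y = rng.uniform(size=10)
        m = GradientBoostedRSA(
            n_stages=3, learning_rate=1.0, loss="squared", max_depth=1,
            min_samples_leaf=1, clip_predictions=False,
        ).fit(X, y)
        ref = naive_stump_boost(X, y, 3, 1.0)
        for got, want in zip(m.staged_predict(X), ref):
            assert np.abs(got - want).max() < 1e-10

    def test_training_loss_non_increasing_both_losses(self, rng):
        X = rng.uniform(size=(80, 4))
        y = np.clip(X[:, 0] * 0.8 + rng.normal(0, 0.1, 80), 0, 1)
        for loss in ("huber", "squared"):
            m = GradientBoostedRSA(
                n_stages=25, learning_rate=0.5, loss=loss, max_depth=2,
                min_samples_leaf=2,
            ).fit(X, y)
            # per-stage comparison at that stage's delta
            F = np.full(80, m.f0_)
            for tree, delta in zip(m.stages_, m.deltas_):
                F_new = F + m.learning_rate * tree.predict(X)
                if loss == "huber":
                    before = huber_loss(y, F, delta)
                    after = huber_loss(y, F_new, delta)
                else:
                    before = 0.5 * np.sum((y - F) ** 2)
                    after = 0.5 * np.sum((y - F_new) ** 2)
                assert after <= before + 1e-9
                F = F_new

    def test_overfit_reproduces_targets(self, rng):
        X = rng.uniform(size=(25, 3))
        y = rng.uniform(size=25)
        m = GradientBoostedRSA(
            n_stages=60, learning_rate=1.0, loss="squared", max_depth=8,
            min_samples_leaf=1,
        ).fit(X, y)
        assert np.abs(m.predict(X) - y).max() < 1e-9

    def test_deterministic_refit(self, rng):
        X = rng.uniform(size=(60, 5))
        y = np.clip(0.5 + X[:, 1] - X[:, 2] + rng.normal(0, 0.05, 60), 0, 1)
        a = GradientBoostedRSA(n_stages=15, max_depth=3).fit(X, y)
        b = GradientBoostedRSA(n_stages=15, max_depth=3).fit(X, y)
        assert json.dumps(a.to_dict()) == json.dumps(b.to_dict())
        Xq = rng.uniform(size=(30, 5))
        assert np.array_equal(a.predict(Xq), b.predict(Xq))

    def test_leaf_regions_partition(self, rng):
        X = rng.uniform(size=(200, 4))
        y = np.clip(X[:, 0] + rng.normal(0, 0.1, 200), 0, 1)
        m = GradientBoostedRSA(n_stages=5, max_depth=3).fit(X, y)
        pts = rng.uniform(-2, 3, size=(10_000, 4))
        for tree in m.stages_:
            leaves = tree.apply(pts)
            leaf_ids = set(tree.leaf_node_ids().tolist())
            assert set(np.unique(leaves)).issubset(leaf_ids)
            assert np.isfinite(tree.value[leaves]).all()

    def test_predictions_clipped_to_unit_interval(self, rng):
        X = rng.uniform(size=(50, 2))
        y = rng.uniform(size=50)
        m = GradientBoostedRSA(n_stages=20, learning_rate=1.0).fit(X, y)
        out = m.predict(rng.uniform(-5, 5, size=(100, 2)))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_column_mismatch_error_names_widths(self, rng):
        X = rng.uniform(size=(20, 3))
        m = GradientBoostedRSA(n_stages=2).fit(X, rng.uniform(size=20))
        with pytest.raises(ValueError, match="3.*4|expects 3"):
            m.predict(rng.uniform(size=(5, 4)))

    def test_non_finite_rejected(self):
        X = np.array([[0.0], [np.nan]])
        with pytest.raises(ValueError):
            GradientBoostedRSA(n_stages=1).fit(X, [0.1, 0.2])

    def test_targets_outside_unit_interval_rejected_when_clipping(self):
        X = np.array([[0.0], [1.0]])
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            GradientBoostedRSA(n_stages=1).fit(X, [0.0, 1.5])
        GradientBoostedRSA(n_stages=1, clip_predictions=False).fit(X, [0.0, 1.5])


class TestFeatureImportance:
    def test_planted_signal_dominates(self, rng):
        X = rng.uniform(size=(300, 5))
        y = np.clip(X[:, 0] + rng.normal(0, 0.02, 300), 0, 1)
        m = GradientBoostedRSA(n_stages=30, max_depth=2).fit(X, y)
        imp = m.feature_importances_
        assert imp[0] > imp[1:].max()
        assert imp.sum() == pytest.approx(1.0)
        assert (imp >= 0).all()

    def test_no_splits_gives_zeros(self):
        X = np.zeros((10, 3))
        m = GradientBoostedRSA(n_stages=3).fit(X, np.full(10, 0.5))
        assert np.allclose(m.feature_importances_, 0.0)

    def test_single_split_model(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        m = GradientBoostedRSA(
            n_stages=1, learning_rate=1.0, loss="squared", max_depth=1,
            min_samples_leaf=1,
        ).fit(X, y)
        assert m.feature_importances_[0] == pytest.approx(1.0)


class TestSerialization:
    def test_json_round_trip_is_lossless(self, rng, tmp_path):
        X = rng.uniform(size=(60, 4))
        y = np.clip(X[:, 0] * 0.7 + rng.normal(0, 0.05, 60), 0, 1)
        m = GradientBoostedRSA(n_stages=12, max_depth=3).fit(X, y)
        path = tmp_path / "model.json"
        m.to_json(path)
        m2 = GradientBoostedRSA.from_json(path)
        Xq = rng.uniform(size=(40, 4))
        assert np.array_equal(m.predict(Xq), m2.predict(Xq))
        assert m2.f0_ == m.f0_
        assert json.dumps(m.to_dict()) == json.dumps(m2.to_dict())

    def test_version_check(self):
        with pytest.raises(ValueError, match="version"):
            GradientBoostedRSA.from_dict({"format_version": 99})


class TestSklearnCrossCheck:
    def test_squared_loss_agrees_with_sklearn_gbr(self, rng):
        """Independent oracle: scikit-learn's gradient boosting with squared
        loss implements the same CART/shrinkage algorithm."""
        from sklearn.ensemble import GradientBoostingRegressor

        X = rng.normal(size=(150, 4))
        y = rng.uniform(size=150)
        ours = GradientBoostedRSA(
            n_stages=20, learning_rate=0.3, loss="squared", max_depth=2,
            min_samples_leaf=3, clip_predictions=False,
        ).fit(X, y)
        sk = GradientBoostingRegressor(
            n_estimators=20, learning_rate=0.3, max_depth=2,
            min_samples_leaf=3,
        ).fit(X, y)
        assert np.abs(ours.predict(X) - sk.predict(X)).max() < 1e-8
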