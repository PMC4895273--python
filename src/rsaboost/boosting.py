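"""Gradient-boosted regression trees with a robust Huber loss.

This module implements the stagewise additive model

    F_M(x) = F_0 + nu * sum_m  u_m(leaf_m(x))

where each stage fits a CART regression tree to the loss-gradient
pseudo-residuals and replaces its leaf means by per-leaf line-search
updates.  The default loss is the Huber loss

    psi(y, F) = (y-F)^2 / 2            if |y-F| <= delta
                delta (|y-F| - delta/2) otherwise

whose transition point ``delta`` is re-estimated every iteration as the
``huber_alpha`` quantile of the absolute residuals.  Per-leaf updates are the
exact minimizers of the leaf loss (the Huber location M-estimate for the
Huber loss, the mean residual for squared loss); a separate global stage
weight is therefore unnecessary — the per-leaf constants subsume it.

The learner is exposed as the scikit-learn style estimator
:class:`GradientBoostedRSA`; the module-level functions are thin wrappers
used by tests and by callers who want the primitives directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "LossFunction",
    "TrainConfig",
    "RegressionTree",
    "GradientBoostedRSA",
    "initial_value",
    "pseudo_residuals",
    "huber_delta",
    "huber_loss",
    "fit_tree",
    "leaf_updates",
    "fit",
    "predict",
    "feature_importance",
]

_DELTA_FLOOR = 1e-12
_SERIAL_VERSION = 1


# --------------------------------------------------------------------------
# loss primitives
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LossFunction:
    """Boosting loss: ``huber`` (robust, default) or ``squared``.

    ``alpha`` is the quantile of absolute residuals used to set the Huber
    transition point delta at each iteration; ignored for squared loss.
    """

    kind: str = "huber"
    alpha: float = 0.9

    def __post_init__(self) -> None:
        if self.kind not in ("huber", "squared"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")


def huber_loss(y: np.ndarray, f: np.ndarray, delta: float) -> float:
    """Total Huber loss sum psi(y_i, f_i) at transition point ``delta``."""
    r = np.abs(np.asarray(y, float) - np.asarray(f, float))
    quad = r <= delta
    out = np.where(quad, 0.5 * r * r, delta * (r - 0.5 * delta))
    return float(out.sum())


def initial_value(y: np.ndarray, loss: LossFunction) -> float:
    """Constant minimizing the total loss: mean for squared, median for Huber.

    The Huber minimizer over a constant depends on delta, which is undefined
    before the first iteration; the median (the small-delta limit) is used.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty training set")
    if loss.kind == "squared":
        return float(np.mean(y))
    return float(np.median(y))


def huber_delta(residuals: np.ndarray, alpha: float) -> float:
    """Transition point: alpha-quantile of |residuals| (linear interpolation),
    floored at a small epsilon so degenerate fits keep a valid loss."""
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size == 0:
        raise ValueError("empty residual vector")
    return max(float(np.quantile(np.abs(residuals), alpha)), _DELTA_FLOOR)


def pseudo_residuals(
    y: np.ndarray, f: np.ndarray, loss: LossFunction, delta: float = 0.0
) -> np.ndarray:
    """Negative loss gradient at the current fit.

    Squared loss: ``y - f``.  Huber loss: ``y - f`` clipped to ``[-delta,
    delta]`` (the raw residual inside the quadratic zone, ``delta * sign``
    outside it).
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape:
        raise ValueError(f"length mismatch: y has {y.shape}, f has {f.shape}")
    r = y - f
    if loss.kind == "squared":
        return r
    if delta <= 0:
        raise ValueError("delta must be positive for the Huber loss")
    return np.clip(r, -delta, delta)


def _huber_location(r: np.ndarray, delta: float) -> float:
    """Exact minimizer of ``sum_i huber(r_i - u)`` over the constant ``u``.

    The derivative g(u) = sum_i clip(u - r_i, -delta, delta) is piecewise
    linear and non-decreasing with breakpoints at r_i +- delta; the minimizer
    is its root.  A flat zero plateau (all residuals clipped, balanced sides)
    is resolved to its midpoint.
    """
    r = np.asarray(r, dtype=float)
    if r.size == 1:
        return float(r[0])
    bps = np.unique(np.concatenate([r - delta, r + delta]))
    # vectorized g at every breakpoint
    g = np.clip(bps[:, None] - r[None, :], -delta, delta).sum(axis=1)
    tol = 1e-12 * max(1.0, delta) * r.size
    i = int(np.searchsorted(g, -tol, side="right"))  # first index with g > -tol
    if i >= bps.size:
        return float(bps[-1])
    if abs(g[i]) <= tol:
        j = i
        while j + 1 < bps.size and abs(g[j + 1]) <= tol:
            j += 1
        return float(0.5 * (bps[i] + bps[j]))
    if i == 0:
        return float(bps[0])
    # linear interpolation to the root between bps[i-1] and bps[i]
    g0, g1 = g[i - 1], g[i]
    return float(bps[i - 1] + (0.0 - g0) * (bps[i] - bps[i - 1]) / (g1 - g0))


# --------------------------------------------------------------------------
# CART regression tree
# --------------------------------------------------------------------------

@dataclass
class RegressionTree:
    """Binary axis-aligned regression tree in flat-array form.

    ``children_left[i] == -1`` marks a leaf; internal nodes route
    ``x[feature[i]] <= threshold[i]`` to the left child.  Leaf regions
    partition the input space: every input reaches exactly one leaf.
    """

    feature: np.ndarray          # int, -1 at leaves
    threshold: np.ndarray        # float, nan at leaves
    children_left: np.ndarray    # int, -1 at leaves
    children_right: np.ndarray   # int, -1 at leaves
    value: np.ndarray            # float leaf values (nan at internal nodes)
    n_samples: np.ndarray        # int per node
    split_gain: np.ndarray = field(default=None)  # SSE reduction per split

    @property
    def n_leaves(self) -> int:
        return int(np.sum(self.children_left == -1))

    @property
    def n_nodes(self) -> int:
        return int(self.feature.size)

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf node index for every row of ``X``."""
        X = np.asarray(X, dtype=float)
        node = np.zeros(X.shape[0], dtype=np.intp)
        while True:
            internal = self.children_left[node] != -1
            if not internal.any():
                return node
            idx = np.nonzero(internal)[0]
            f = self.feature[node[idx]]
            go_left = X[idx, f] <= self.threshold[node[idx]]
            node[idx] = np.where(
                go_left, self.children_left[node[idx]], self.children_right[node[idx]]
            )

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.value[self.apply(X)]

    def set_leaf_values(self, leaf_nodes: np.ndarray, values: np.ndarray) -> None:
        self.value = self.value.copy()
        self.value[leaf_nodes] = values

    def leaf_node_ids(self) -> np.ndarray:
        return np.nonzero(self.children_left == -1)[0]


def _best_split(
    X: np.ndarray,
    t: np.ndarray,
    min_samples_leaf: int,
    sorted_idx: Optional[np.ndarray] = None,
) -> Optional[Tuple[float, int, float]]:
    """Exhaustive CART split scan: (SSE reduction, feature, threshold).

    Candidate thresholds are midpoints between consecutive distinct sorted
    values.  Ties break to the lowest feature index, then lowest threshold
    (argmin over ascending thresholds picks the first optimum).

    ``sorted_idx`` (one column per feature, sample indices in ascending
    feature order) lets callers reuse a presorted order across tree nodes.
    """
    p = X.shape[1]
    if sorted_idx is None:
        sorted_idx = np.argsort(X, axis=0, kind="stable")
    n = sorted_idx.shape[0]
    if n < 2 * min_samples_leaf or p == 0:
        return None
    cols = np.arange(p)
    xs = X[sorted_idx, cols[None, :]]
    ts = t[sorted_idx]
    cs = np.cumsum(ts, axis=0)
    cs2 = np.cumsum(ts * ts, axis=0)
    total = cs[-1]
    total2 = cs2[-1]
    k = np.arange(1, n, dtype=float)[:, None]
    left_s, left_s2 = cs[:-1], cs2[:-1]
    sse = (left_s2 - left_s**2 / k) + (
        (total2 - left_s2) - (total - left_s) ** 2 / (n - k)
    )
    valid = (xs[1:] > xs[:-1]) & (k >= min_samples_leaf) & ((n - k) >= min_samples_leaf)
    sse = np.where(valid, sse, np.inf)
    best_row = np.argmin(sse, axis=0)
    best_per_feature = sse[best_row, np.arange(p)]
    f = int(np.argmin(best_per_feature))
    if not np.isfinite(best_per_feature[f]):
        return None
    i = int(best_row[f])
    parent_sse = float(total2[f] - total[f] ** 2 / n)
    gain = parent_sse - float(best_per_feature[f])
    threshold = float(0.5 * (xs[i, f] + xs[i + 1, f]))
    return gain, f, threshold


def fit_tree(
    X: np.ndarray,
    targets: np.ndarray,
    cfg: "TrainConfig",
    presorted: Optional[np.ndarray] = None,
) -> RegressionTree:
    """Greedy top-down least-squares regression tree.

    Leaf value = mean of targets in the region; splits honour ``max_depth``
    and ``min_samples_leaf``; constant targets yield a single leaf.
    ``presorted`` (the per-column stable argsort of X) can be shared across
    the boosting loop since the design matrix never changes.
    """
    X = np.asarray(X, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("empty training set for tree fit")
    if X.shape[0] != targets.shape[0]:
        raise ValueError("row count of X does not match targets")

    feature: List[int] = []
    threshold: List[float] = []
    left: List[int] = []
    right: List[int] = []
    value: List[float] = []
    n_samples: List[int] = []
    gains: List[float] = []

    def new_node() -> int:
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        value.append(np.nan)
        n_samples.append(0)
        gains.append(0.0)
        return len(feature) - 1

    n_total, p = X.shape
    in_left = np.zeros(n_total, dtype=bool)  # scratch partition mask

    def build(sorted_idx: np.ndarray, depth: int) -> int:
        # sorted_idx: (n_node, p) sample indices, each column in ascending
        # order of its feature — partitioned stably down the tree so nodes
        # never re-sort.
        node = new_node()
        idx = sorted_idx[:, 0]
        t = targets[idx]
        n_samples[node] = int(idx.size)
        if (
            depth >= cfg.max_depth
            or idx.size < 2 * cfg.min_samples_leaf
            or np.all(t == t[0])
        ):
            value[node] = float(t.mean())
            return node
        split = _best_split(X, targets, cfg.min_samples_leaf, sorted_idx)
        if split is None or split[0] <= 0.0:
            value[node] = float(t.mean())
            return node
        gain, f, thr = split
        feature[node] = f
        threshold[node] = thr
        gains[node] = gain
        go_left = X[idx, f] <= thr
        in_left[idx] = go_left
        mask = in_left[sorted_idx]
        n_left = int(go_left.sum())
        left_sorted = sorted_idx.T[mask.T].reshape(p, n_left).T
        right_sorted = sorted_idx.T[~mask.T].reshape(p, idx.size - n_left).T
        left[node] = build(left_sorted, depth + 1)
        right[node] = build(right_sorted, depth + 1)
        return node

    if presorted is None:
        presorted = np.argsort(X, axis=0, kind="stable").astype(np.intp)
    build(presorted, 0)
    return RegressionTree(
        feature=np.asarray(feature, dtype=np.intp),
        threshold=np.asarray(threshold, dtype=float),
        children_left=np.asarray(left, dtype=np.intp),
        children_right=np.asarray(right, dtype=np.intp),
        value=np.asarray(value, dtype=float),
        n_samples=np.asarray(n_samples, dtype=np.intp),
        split_gain=np.asarray(gains, dtype=float),
    )


def leaf_updates(
    tree: RegressionTree,
    y: np.ndarray,
    f: np.ndarray,
    loss: LossFunction,
    delta: float = 0.0,
    X: Optional[np.ndarray] = None,
    leaf_of_sample: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-leaf line-search updates.

    Returns ``(leaf_node_ids, update_values)``.  Squared loss: mean residual
    in the leaf (exact line search).  Huber loss: exact minimizer of the
    leaf's Huber loss over a constant shift (see :func:`_huber_location`).
    """
    if leaf_of_sample is None:
        if X is None:
            raise ValueError("either X or leaf_of_sample is required")
        leaf_of_sample = tree.apply(X)
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    r = y - f
    leaf_ids = tree.leaf_node_ids()
    updates = np.empty(leaf_ids.size, dtype=float)
    for j, leaf in enumerate(leaf_ids):
        rl = r[leaf_of_sample == leaf]
        if rl.size == 0:  # unreachable by construction; keep the leaf inert
            updates[j] = 0.0
        elif loss.kind == "squared":
            updates[j] = float(rl.mean())
        else:
            updates[j] = _huber_location(rl, delta)
    return leaf_ids, updates


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters for the boosting loop."""

    n_stages: int = 800
    nu: float = 0.1
    max_depth: int = 4
    min_samples_leaf: int = 5
    loss: str = "huber"
    huber_alpha: float = 0.9
    clip_predictions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stages < 0:
            raise ValueError("n_stages must be >= 0")
        if not (0.0 < self.nu <= 1.0):
            raise ValueError("nu must lie in (0, 1]")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")


class GradientBoostedRSA(RegressorMixin, BaseEstimator):
    """Gradient-boosted regression trees for relative solvent accessibility.

    Stagewise additive model: the fit starts from the constant loss minimizer
    ``f0_`` and adds ``n_stages`` depth-capped CART trees, each fitted by
    least squares to the pseudo-residuals of the running fit and finished
    with exact per-leaf line-search updates scaled by the shrinkage
    ``learning_rate``.  Training is fully deterministic given the data and
    parameters (no subsampling).

    Parameters
    ----------
    n_stages : number of boosting iterations M (default 800, the grid-search
        optimum on the reference benchmark).
    learning_rate : shrinkage nu in (0, 1].
    loss : "huber" (robust, default) or "squared".
    huber_alpha : quantile of |residuals| setting the Huber transition point
        delta each iteration.
    max_depth : depth cap of each tree (default 4).
    min_samples_leaf : minimum samples per leaf (default 5).
    clip_predictions : clip outputs to [0, 1], the RSA range (default True).

    Attributes
    ----------
    f0_ : initial constant fit.
    stages_ : list of fitted :class:`RegressionTree` (leaf values hold the
        unshrunk per-leaf updates).
    deltas_ : Huber transition point used at each stage.
    train_loss_ : total training loss after each stage, evaluated at that
        stage's delta.
    feature_importances_ : normalized total SSE reduction per feature.
    """

    def __init__(
        self,
        n_stages: int = 800,
        learning_rate: float = 0.1,
        loss: str = "huber",
        huber_alpha: float = 0.9,
        max_depth: int = 4,
        min_samples_leaf: int = 5,
        clip_predictions: bool = True,
    ):
        self.n_stages = n_stages
        self.learning_rate = learning_rate
        self.loss = loss
        self.huber_alpha = huber_alpha
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.clip_predictions = clip_predictions

    # -- fitting -----------------------------------------------------------

    def _loss(self) -> LossFunction:
        return LossFunction(kind=self.loss, alpha=self.huber_alpha)

    def _cfg(self) -> TrainConfig:
        return TrainConfig(
            n_stages=self.n_stages,
            nu=self.learning_rate,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            loss=self.loss,
            huber_alpha=self.huber_alpha,
            clip_predictions=self.clip_predictions,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GradientBoostedRSA":
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if y.size == 0:
            raise ValueError("empty training set")
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise ValueError("non-finite values in features or targets")
        if self.clip_predictions and (y.min() < 0.0 or y.max() > 1.0):
            raise ValueError(
                "targets must lie in [0, 1] when clip_predictions is on; "
                "set clip_predictions=False for unbounded regression"
            )
        loss = self._loss()
        cfg = self._cfg()

        self.n_features_in_ = X.shape[1]
        self.f0_ = initial_value(y, loss)
        f = np.full(y.shape, self.f0_, dtype=float)
        stages: List[RegressionTree] = []
        deltas: List[float] = []
        losses: List[float] = []
        gains = np.zeros(X.shape[1], dtype=float)
        presorted = np.argsort(X, axis=0, kind="stable").astype(np.intp)

        for _ in range(self.n_stages):
            r = y - f
            if loss.kind == "huber":
                delta = huber_delta(r, loss.alpha)
            else:
                delta = 0.0
            grad = pseudo_residuals(y, f, loss, delta)
            tree = fit_tree(X, grad, cfg, presorted=presorted)
            leaf_of_sample = tree.apply(X)
            leaf_ids, updates = leaf_updates(
                tree, y, f, loss, delta, leaf_of_sample=leaf_of_sample
            )
            tree.set_leaf_values(leaf_ids, updates)
            gains += np.bincount(
                tree.feature[tree.feature >= 0],
                weights=tree.split_gain[tree.feature >= 0],
                minlength=X.shape[1],
            )
            f = f + self.learning_rate * tree.value[leaf_of_sample]
            stages.append(tree)
            deltas.append(delta)
            if loss.kind == "huber":
                losses.append(huber_loss(y, f, delta))
            else:
                losses.append(float(0.5 * np.sum((y - f) ** 2)))

        self.stages_ = stages
        self.deltas_ = np.asarray(deltas, dtype=float)
        self.train_loss_ = np.asarray(losses, dtype=float)
        total = gains.sum()
        self.feature_importances_ = gains / total if total > 0 else gains
        return self

    # -- prediction --------------------------------------------------------

    def _raw_predict(self, X: np.ndarray) -> np.ndarray:
        pred = np.full(X.shape[0], self.f0_, dtype=float)
        for tree in self.stages_:
            pred += self.learning_rate * tree.predict(X)
        return pred

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "stages_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature count mismatch: model expects {self.n_features_in_} "
                f"columns, got {X.shape[1]}"
            )
        return X

    def predict(self, X: np.ndarray, clip: Optional[bool] = None) -> np.ndarray:
        X = self._check_X(X)
        pred = self._raw_predict(X)
        do_clip = self.clip_predictions if clip is None else clip
        return np.clip(pred, 0.0, 1.0) if do_clip else pred

    def staged_predict(
        self, X: np.ndarray, clip: Optional[bool] = None
    ) -> Iterator[np.ndarray]:
        """Prediction after each boosting stage (M = 1 .. n_stages)."""
        X = self._check_X(X)
        do_clip = self.clip_predictions if clip is None else clip
        pred = np.full(X.shape[0], self.f0_, dtype=float)
        for tree in self.stages_:
            pred = pred + self.learning_rate * tree.predict(X)
            yield np.clip(pred, 0.0, 1.0) if do_clip else pred

    def predict_truncated(
        self, X: np.ndarray, n_stages: int, clip: Optional[bool] = None
    ) -> np.ndarray:
        """Prediction of the model truncated to its first ``n_stages`` trees."""
        X = self._check_X(X)
        if not (0 <= n_stages <= len(self.stages_)):
            raise ValueError("n_stages out of range")
        pred = np.full(X.shape[0], self.f0_, dtype=float)
        for tree in self.stages_[:n_stages]:
            pred += self.learning_rate * tree.predict(X)
        do_clip = self.clip_predictions if clip is None else clip
        return np.clip(pred, 0.0, 1.0) if do_clip else pred

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "stages_")
        return {
            "format_version": _SERIAL_VERSION,
            "params": self.get_params(),
            "n_features_in": int(self.n_features_in_),
            "f0": self.f0_,
            "deltas": self.deltas_.tolist(),
            "train_loss": self.train_loss_.tolist(),
            "feature_importances": self.feature_importances_.tolist(),
            "stages": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": [
                        None if np.isnan(v) else v for v in t.threshold
                    ],
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "value": [None if np.isnan(v) else v for v in t.value],
                    "n_samples": t.n_samples.tolist(),
                    "split_gain": t.split_gain.tolist(),
                }
                for t in self.stages_
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "GradientBoostedRSA":
        if doc.get("format_version") != _SERIAL_VERSION:
            raise ValueError(
                f"unsupported model format version {doc.get('format_version')!r}"
            )
        est = cls(**doc["params"])
        est.n_features_in_ = int(doc["n_features_in"])
        est.f0_ = float(doc["f0"])
        est.deltas_ = np.asarray(doc["deltas"], dtype=float)
        est.train_loss_ = np.asarray(doc["train_loss"], dtype=float)
        est.feature_importances_ = np.asarray(
            doc["feature_importances"], dtype=float
        )
        est.stages_ = [
            RegressionTree(
                feature=np.asarray(t["feature"], dtype=np.intp),
                threshold=np.asarray(
                    [np.nan if v is None else v for v in t["threshold"]], dtype=float
                ),
                children_left=np.asarray(t["children_left"], dtype=np.intp),
                children_right=np.asarray(t["children_right"], dtype=np.intp),
                value=np.asarray(
                    [np.nan if v is None else v for v in t["value"]], dtype=float
                ),
                n_samples=np.asarray(t["n_samples"], dtype=np.intp),
                split_gain=np.asarray(t["split_gain"], dtype=float),
            )
            for t in doc["stages"]
        ]
        return est

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "GradientBoostedRSA":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------

def fit(X: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> GradientBoostedRSA:
    """Fit a boosted model under ``cfg`` (functional form of the estimator)."""
    est = GradientBoostedRSA(
        n_stages=cfg.n_stages,
        learning_rate=cfg.nu,
        loss=cfg.loss,
        huber_alpha=cfg.huber_alpha,
        max_depth=cfg.max_depth,
        min_samples_leaf=cfg.min_samples_leaf,
        clip_predictions=cfg.clip_predictions,
    )
    return est.fit(X, y)


def predict(model: GradientBoostedRSA, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def feature_importance(model: GradientBoostedRSA) -> np.ndarray:
    return model.feature_importances_
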