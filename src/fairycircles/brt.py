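"""Boosted regression trees for presence/absence niche modeling.

Stagewise logistic (binomial-deviance) gradient boosting with small
regression trees, written from first principles:

* trees are grown best-first to at most ``tree_complexity`` splits using
  least-squares split gain on the pseudo-residuals r = y - p;
* each tree is fit on a ``bag_fraction`` subsample; leaf values are one
  Newton step sum(r) / sum(p (1 - p)) over in-bag leaf members;
* the ensemble prediction is logistic(F0 + lr * sum of tree outputs) with
  F0 the log-odds of training prevalence.

On top of the learner: rank-based AUC, stratified cross-validated AUC,
per-variable relative influence (share of total squared-error improvement,
normalized to 100), 1-SE backward simplification, partial dependence on
the link scale, grid prediction, and a pairwise interaction size measured
as the variance of the non-additive residual of the joint partial
dependence surface (scaled by 1000; only ordering is meaningful).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "BRTConfig",
    "RegressionTree",
    "BRTModel",
    "fit_brt",
    "auc",
    "cv_auc",
    "cv_deviance",
    "relative_influence",
    "simplify",
    "partial_dependence",
    "pairwise_interaction",
    "predict_grid",
]

_EPS = 1e-12


@dataclass(frozen=True)
class BRTConfig:
    """Boosting hyperparameters.

    Defaults mirror the study protocol: 8 splits per tree, learning rate
    5e-4 (with enough trees that lr * n_trees is approximately 3.6),
    bagging fraction 0.5, binomial deviance, 10 CV folds.
    """

    tree_complexity: int = 8
    learning_rate: float = 0.0005
    bag_fraction: float = 0.5
    n_trees: int = 7200
    cv_folds: int = 10
    min_samples_leaf: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.tree_complexity < 1:
            raise ValueError("tree_complexity must be >= 1")
        if self.n_trees <= 0:
            raise ValueError("n_trees must be positive")


class RegressionTree:
    """Array-backed binary regression tree (at most tree_complexity splits).

    feature[i] >= 0 marks an internal node with its split variable;
    feature[i] == -1 marks a leaf whose prediction is value[i].
    ``improvement`` stores the squared-error reduction of each split, the
    raw material of relative influence.
    """

    __slots__ = ("feature", "threshold", "left", "right", "value", "improvement")

    def __init__(self) -> None:
        self.feature = np.array([-1], dtype=np.int32)
        self.threshold = np.array([0.0])
        self.left = np.array([-1], dtype=np.int32)
        self.right = np.array([-1], dtype=np.int32)
        self.value = np.array([0.0])
        self.improvement = np.array([0.0])

    @property
    def n_splits(self) -> int:
        return int((self.feature >= 0).sum())

    def _add_node(self) -> int:
        self.feature = np.append(self.feature, -1)
        self.threshold = np.append(self.threshold, 0.0)
        self.left = np.append(self.left, -1)
        self.right = np.append(self.right, -1)
        self.value = np.append(self.value, 0.0)
        self.improvement = np.append(self.improvement, 0.0)
        return len(self.feature) - 1

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index for every row of X."""
        node = np.zeros(len(X), dtype=np.int32)
        while True:
            feat = self.feature[node]
            internal = feat >= 0
            if not internal.any():
                return node
            rows = np.nonzero(internal)[0]
            sub = node[rows]
            go_left = X[rows, self.feature[sub]] <= self.threshold[sub]
            node[rows] = np.where(go_left, self.left[sub], self.right[sub])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.value[self.apply(X)]


def _best_split(
    X: np.ndarray, r: np.ndarray, idx: np.ndarray, min_leaf: int
) -> tuple[float, int, float, np.ndarray, np.ndarray] | None:
    """Best least-squares split of node members ``idx`` over all features.

    Returns (gain, feature, threshold, left_idx, right_idx) or None.
    Vectorized across features: one argsort/cumsum pass per node.
    """
    m = idx.size
    if m < 2 * min_leaf:
        return None
    vals = X[idx]  # (m, d)
    res = r[idx]
    order = np.argsort(vals, axis=0, kind="stable")
    sv = np.take_along_axis(vals, order, axis=0)
    sr = res[order]  # (m, d)
    cs = np.cumsum(sr, axis=0)
    total = cs[-1, 0]
    nl = np.arange(1, m, dtype=float)[:, None]
    nr = m - nl
    sum_l = cs[:-1]
    with np.errstate(invalid="ignore"):
        score = sum_l**2 / nl + (total - sum_l) ** 2 / nr
    valid = (sv[1:] > sv[:-1]) & (nl >= min_leaf) & (nr >= min_leaf)
    score = np.where(valid, score, -np.inf)
    flat = int(np.argmax(score))
    best = score.flat[flat]
    if not np.isfinite(best):
        return None
    pos, feat = np.unravel_index(flat, score.shape)
    gain = float(best - total**2 / m)
    if gain <= 0:
        return None
    thr = float(0.5 * (sv[pos, feat] + sv[pos + 1, feat]))
    left_mask = vals[:, feat] <= thr
    return gain, int(feat), thr, idx[left_mask], idx[~left_mask]


def _fit_tree(
    X: np.ndarray, r: np.ndarray, p: np.ndarray, bag: np.ndarray, config: BRTConfig
) -> RegressionTree:
    """Grow one tree on the bagged rows, best-first, then replace leaf means
    by one Newton step for binomial deviance."""
    tree = RegressionTree()
    # candidate splits per leaf: node_id -> (gain, feat, thr, li, ri)
    members = {0: bag}
    cand = {}
    s = _best_split(X, r, bag, config.min_samples_leaf)
    if s is not None:
        cand[0] = s
    for _ in range(config.tree_complexity):
        if not cand:
            break
        node = max(cand, key=lambda k: cand[k][0])
        gain, feat, thr, li, ri = cand.pop(node)
        lid = tree._add_node()
        rid = tree._add_node()
        tree.feature[node] = feat
        tree.threshold[node] = thr
        tree.left[node] = lid
        tree.right[node] = rid
        tree.improvement[node] = gain
        del members[node]
        members[lid] = li
        members[rid] = ri
        for nid, m_idx in ((lid, li), (rid, ri)):
            s = _best_split(X, r, m_idx, config.min_samples_leaf)
            if s is not None:
                cand[nid] = s
    # Newton leaf values over in-bag members
    for nid, m_idx in members.items():
        num = r[m_idx].sum()
        den = (p[m_idx] * (1.0 - p[m_idx])).sum()
        tree.value[nid] = num / max(den, _EPS)
    return tree


def _as_matrix(
    X: pd.DataFrame | np.ndarray, feature_names: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-D")
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(arr.shape[1])]
    return arr, list(feature_names)


@dataclass
class BRTModel:
    """Fitted boosted ensemble: logistic(F0 + lr * sum of tree outputs)."""

    intercept: float
    trees: list[RegressionTree]
    config: BRTConfig
    feature_names: list[str]
    train_means: np.ndarray
    deviance_trace: np.ndarray = field(repr=False, default=None)

    def _matrix(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise KeyError(f"missing covariates: {missing}")
            return X[self.feature_names].to_numpy(dtype=float)
        arr = np.asarray(X, dtype=float)
        if arr.shape[1] != len(self.feature_names):
            raise ValueError("covariate count mismatch")
        return arr

    def predict_link(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Log-odds scale prediction F(x)."""
        arr = self._matrix(X)
        F = np.full(len(arr), self.intercept)
        lr = self.config.learning_rate
        for tree in self.trees:
            F += lr * tree.predict(arr)
        return F

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        return _sigmoid(self.predict_link(X))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_brt(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    config: BRTConfig | None = None,
    feature_names: Sequence[str] | None = None,
) -> BRTModel:
    """Fit the boosted presence/absence model.

    Deterministic given (X, y, config): all bagging randomness flows from
    ``config.seed``. Raises on single-class targets.
    """
    if config is None:
        config = BRTConfig()
    arr, names = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != len(arr):
        raise ValueError("X and y length mismatch")
    if np.isnan(arr).any():
        raise ValueError("missing covariate values are not supported")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        if len(classes) < 2:
            raise ValueError("y must contain both classes")
        raise ValueError("y must be binary 0/1")
    n = len(y)
    prevalence = y.mean()
    F0 = float(np.log(prevalence / (1.0 - prevalence)))
    rng = np.random.default_rng(config.seed)
    n_bag = max(2 * config.min_samples_leaf, int(round(config.bag_fraction * n)))
    n_bag = min(n_bag, n)

    F = np.full(n, F0)
    trees: list[RegressionTree] = []
    trace = np.empty(config.n_trees)
    for t in range(config.n_trees):
        p = _sigmoid(F)
        r = y - p
        bag = (
            np.arange(n)
            if n_bag == n
            else rng.choice(n, size=n_bag, replace=False)
        )
        tree = _fit_tree(arr, r, p, bag, config)
        trees.append(tree)
        F += config.learning_rate * tree.predict(arr)
        trace[t] = _binomial_deviance(y, _sigmoid(F))
    return BRTModel(
        intercept=F0,
        trees=trees,
        config=config,
        feature_names=names,
        train_means=arr.mean(axis=0),
        deviance_trace=trace,
    )


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) ROC AUC; ties receive half credit."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _stratified_folds(
    y: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    return list(skf.split(np.zeros(len(y)), y))


def _cv_scores(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    config: BRTConfig,
    feature_names: Sequence[str] | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Held-out (labels, predicted probabilities) per stratified fold."""
    if config.cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    arr, names = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=float).ravel()
    out = []
    for f, (tr, te) in enumerate(_stratified_folds(y, config.cv_folds, config.seed)):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError("a fold lacks both classes; reduce cv_folds")
        fold_cfg = replace(config, seed=config.seed + 1000 * (f + 1))
        model = fit_brt(arr[tr], y[tr], fold_cfg, feature_names=names)
        out.append((y[te], model.predict_proba(arr[te])))
    return out


def cv_auc(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    config: BRTConfig | None = None,
    feature_names: Sequence[str] | None = None,
) -> dict:
    """Stratified k-fold cross-validated AUC: mean, SE and per-fold values."""
    if config is None:
        config = BRTConfig()
    folds = _cv_scores(X, y, config, feature_names)
    aucs = np.array([auc(p, yt) for yt, p in folds])
    return {
        "auc_mean": float(aucs.mean()),
        "auc_se": float(aucs.std(ddof=1) / np.sqrt(len(aucs))),
        "fold_aucs": aucs.tolist(),
    }


def cv_deviance(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    config: BRTConfig | None = None,
    feature_names: Sequence[str] | None = None,
) -> dict:
    """Stratified k-fold cross-validated binomial deviance (mean, SE)."""
    if config is None:
        config = BRTConfig()
    folds = _cv_scores(X, y, config, feature_names)
    devs = np.array([_binomial_deviance(yt, p) for yt, p in folds])
    return {
        "deviance_mean": float(devs.mean()),
        "deviance_se": float(devs.std(ddof=1) / np.sqrt(len(devs))),
        "fold_deviances": devs.tolist(),
    }


def relative_influence(model: BRTModel) -> pd.Series:
    """Per-variable share (%) of total split squared-error improvement,
    summed over every split of every tree and normalized to 100."""
    raw = np.zeros(len(model.feature_names))
    for tree in model.trees:
        internal = tree.feature >= 0
        np.add.at(raw, tree.feature[internal], tree.improvement[internal])
    total = raw.sum()
    if total <= 0:
        # degenerate model with no splits: spread influence uniformly
        raw = np.ones_like(raw)
        total = raw.sum()
    return pd.Series(100.0 * raw / total, index=model.feature_names)


def simplify(
    X: pd.DataFrame,
    y: np.ndarray,
    config: BRTConfig | None = None,
) -> dict:
    """Backward predictor elimination with the 1-SE rule on CV deviance.

    The full elimination path is walked (drop the lowest-influence
    predictor, refit, repeat down to one predictor), recording stratified
    CV deviance for every candidate set on identical folds. The selected
    set is the most parsimonious one whose CV deviance lies within one SE
    of the path minimum. Returns the chosen variables, a model refit on
    them, and the elimination history.
    """
    if config is None:
        config = BRTConfig()
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    current = list(X.columns)
    if len(current) < 2:
        model = fit_brt(X, y, config)
        return {"variables": current, "model": model, "history": []}

    history = []
    while True:
        stats = cv_deviance(X[current], y, config)
        history.append(
            {
                "variables": list(current),
                "cv_deviance": stats["deviance_mean"],
                "cv_deviance_se": stats["deviance_se"],
            }
        )
        if len(current) == 1:
            break
        model = fit_brt(X[current], y, config)
        infl = relative_influence(model)
        current = [v for v in current if v != infl.idxmin()]

    devs = np.array([h["cv_deviance"] for h in history])
    i_min = int(np.argmin(devs))
    threshold = devs[i_min] + history[i_min]["cv_deviance_se"]
    # history is ordered largest set -> smallest; pick the smallest within 1 SE
    best_vars = history[i_min]["variables"]
    for h in history:
        if h["cv_deviance"] <= threshold and len(h["variables"]) <= len(best_vars):
            best_vars = h["variables"]
    final = fit_brt(X[best_vars], y, config)
    return {"variables": best_vars, "model": final, "history": history}


def partial_dependence(
    model: BRTModel, variable: str, grid: np.ndarray
) -> pd.DataFrame:
    """Model response over ``grid`` with every other covariate held at its
    training mean, on the link (log-odds) scale."""
    if variable not in model.feature_names:
        raise KeyError(f"unknown variable {variable!r}")
    grid = np.asarray(grid, dtype=float).ravel()
    j = model.feature_names.index(variable)
    Xg = np.tile(model.train_means, (len(grid), 1))
    Xg[:, j] = grid
    return pd.DataFrame({variable: grid, "link": model.predict_link(Xg)})


def pairwise_interaction(
    model: BRTModel,
    X: pd.DataFrame | np.ndarray,
    pair: tuple[str, str],
    grid_size: int = 10,
) -> float:
    """Interaction size for a variable pair: 1000 x variance of the
    non-additive residual of the joint partial-dependence surface on a
    quantile grid. Zero for additive (e.g. stump) models; symmetric in the
    pair by construction."""
    a, b = pair
    if a == b:
        raise ValueError("pair must name two distinct variables")
    for v in pair:
        if v not in model.feature_names:
            raise KeyError(f"unknown variable {v!r}")
    arr = model._matrix(X)
    ja = model.feature_names.index(a)
    jb = model.feature_names.index(b)
    qs = np.linspace(0.05, 0.95, grid_size)
    ga = np.quantile(arr[:, ja], qs)
    gb = np.quantile(arr[:, jb], qs)
    AA, BB = np.meshgrid(ga, gb, indexing="ij")
    Xg = np.tile(model.train_means, (grid_size**2, 1))
    Xg[:, ja] = AA.ravel()
    Xg[:, jb] = BB.ravel()
    H = model.predict_link(Xg).reshape(grid_size, grid_size)
    resid = H - H.mean(axis=1, keepdims=True) - H.mean(axis=0, keepdims=True) + H.mean()
    return float(1000.0 * resid.var())


def predict_grid(
    model: BRTModel, grids: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Predicted presence probability over co-registered 2-D covariate
    layers (dict name -> array of one common shape)."""
    missing = [v for v in model.feature_names if v not in grids]
    if missing:
        raise KeyError(f"missing covariate layers: {missing}")
    shapes = {np.asarray(grids[v]).shape for v in model.feature_names}
    if len(shapes) != 1:
        raise ValueError("covariate layers must share one shape")
    shape = shapes.pop()
    Xg = np.column_stack(
        [np.asarray(grids[v], dtype=float).ravel() for v in model.feature_names]
    )
    return model.predict_proba(Xg).reshape(shape)
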