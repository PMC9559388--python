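"""Four complementary feature-ranking methods.

* ``rank_lasso`` — one-vs-rest L1-penalized linear fits on standardized
  features; a feature's score is its largest absolute coefficient.
* ``rank_mrmr`` — greedy minimum-redundancy-maximum-relevance (difference
  form) on 3-state discretized features, mutual information in nats.
* ``rank_mcfs`` — Monte-Carlo feature selection: many small decision
  trees on random feature projections; a feature's relative importance
  accumulates its splits' information gains, weighted by the tree's
  class-balanced test accuracy.
* ``rank_gbdt`` — gradient-boosted trees; score = number of splits that
  use the feature across the ensemble.

All rankers are deterministic under their seed and break ties by input
column order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.linear_model import Lasso
from sklearn.metrics import balanced_accuracy_score, mutual_info_score
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .types import FeatureMatrix, RankedList


def _order_by_score(names: list[str], scores: np.ndarray) -> tuple[list[str], list[float]]:
    """Descending score, ties (and exact zeros) in input order."""
    idx = sorted(range(len(names)), key=lambda j: (-scores[j], j))
    return [names[j] for j in idx], [float(scores[j]) for j in idx]


def rank_lasso(X: FeatureMatrix, y, seed: int = 0, alpha: float = 0.01) -> RankedList:
    """L1 one-vs-rest ranking; score = max |coefficient| over classes."""
    values = X.values
    if not np.isfinite(values).all():
        raise ValueError("feature matrix contains non-finite values")
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd[sd == 0.0] = 1.0
    Z = (values - mu) / sd
    y = np.asarray(y)
    classes = np.unique(y)
    scores = np.zeros(Z.shape[1])
    for c in classes:
        target = (y == c).astype(float)
        model = Lasso(alpha=alpha, random_state=seed, max_iter=10_000)
        model.fit(Z, target)
        scores = np.maximum(scores, np.abs(model.coef_))
    feats, ordered_scores = _order_by_score(list(X.feature_names), scores)
    return RankedList(
        method="lasso", features=feats, scores=ordered_scores,
        meta={"alpha": alpha, "seed": seed},
    )


def discretize_three_state(values: np.ndarray) -> np.ndarray:
    """Per column: 0 below mean - sd, 2 above mean + sd, 1 between."""
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    out = np.ones(values.shape, dtype=np.int8)
    out[values < mu - sd] = 0
    out[values > mu + sd] = 2
    return out


def rank_mrmr(X: FeatureMatrix, y, n_select: int | None = None) -> RankedList:
    """Greedy mRMR (relevance minus mean redundancy, MI in nats)."""
    d = len(X.feature_names)
    if n_select is None:
        n_select = d
    if n_select <= 0:
        raise ValueError("n_select must be positive")
    if n_select > d:
        raise ValueError("n_select exceeds feature count")
    disc = discretize_three_state(X.values)
    y = np.asarray(y)
    relevance = np.array(
        [mutual_info_score(disc[:, j], y) for j in range(d)]
    )
    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(d)
    remaining = list(range(d))
    while len(selected) < n_select:
        if selected:
            crit = relevance - redundancy_sum / len(selected)
        else:
            crit = relevance
        best = max(remaining, key=lambda j: (crit[j], -j))
        selected.append(best)
        scores.append(float(crit[best]))
        remaining.remove(best)
        for j in remaining:
            redundancy_sum[j] += mutual_info_score(disc[:, j], disc[:, best])
    names = list(X.feature_names)
    return RankedList(
        method="mrmr",
        features=[names[j] for j in selected],
        scores=scores,
        meta={"n_select": n_select, "discretization": "mean +/- sd"},
    )


@dataclass(frozen=True)
class MCFSParams:
    """Monte-Carlo feature selection parameters.

    ``c`` resamplings x ``s`` projections of ``m_proj`` features each;
    ``u`` and ``v`` exponentiate the tree-accuracy and node-size weights
    in the relative-importance sum.
    """

    c: int = 20
    s: int = 100
    m_proj: int | None = None   # default: ceil(0.05 * n_features)
    u: float = 1.0
    v: float = 1.0
    train_fraction: float = 0.66
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 1 or self.s < 1:
            raise ValueError("c and s must be >= 1")
        if self.m_proj is not None and self.m_proj < 1:
            raise ValueError("m_proj must be >= 1")
        if self.u <= 0 or self.v <= 0:
            raise ValueError("u and v must be positive")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")

    def resolved_m(self, n_features: int) -> int:
        m = self.m_proj if self.m_proj is not None else math.ceil(0.05 * n_features)
        if m > n_features:
            raise ValueError("m_proj exceeds feature count")
        return m


def _tree_feature_gains(tree: DecisionTreeClassifier, v: float) -> dict[int, float]:
    """Per projected feature: sum over its split nodes of
    IG(node) * (n_node / n_root) ** v."""
    t = tree.tree_
    gains: dict[int, float] = {}
    n_root = t.n_node_samples[0]
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:      # leaf
            continue
        n = t.n_node_samples[node]
        ig = t.impurity[node] - (
            t.n_node_samples[left] / n * t.impurity[left]
            + t.n_node_samples[right] / n * t.impurity[right]
        )
        f = int(t.feature[node])
        gains[f] = gains.get(f, 0.0) + max(ig, 0.0) * (n / n_root) ** v
    return gains


def rank_mcfs(X: FeatureMatrix, y, params: MCFSParams | None = None) -> RankedList:
    """Relative-importance ranking over c x s projection trees.

    Features with RI exactly 0 (never credited a split) are dropped from
    the list; their names are recorded in ``meta["dropped"]``.
    """
    if params is None:
        params = MCFSParams()
    d = len(X.feature_names)
    m = params.resolved_m(d)
    y = np.asarray(y)
    values = X.values
    rng = np.random.default_rng(params.seed)
    ri = np.zeros(d)
    for _ in range(params.c):
        split_seed = int(rng.integers(2**31 - 1))
        idx_train, idx_test = train_test_split(
            np.arange(len(y)),
            train_size=params.train_fraction,
            stratify=y,
            random_state=split_seed,
        )
        for _ in range(params.s):
            proj = rng.choice(d, size=m, replace=False)
            tree = DecisionTreeClassifier(
                criterion="entropy",
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(values[np.ix_(idx_train, proj)], y[idx_train])
            pred = tree.predict(values[np.ix_(idx_test, proj)])
            wacc = balanced_accuracy_score(y[idx_test], pred)
            if wacc <= 0.0:
                continue
            weight = wacc ** params.u
            for local_f, gain in _tree_feature_gains(tree, params.v).items():
                ri[proj[local_f]] += weight * gain
    names = list(X.feature_names)
    kept = [j for j in range(d) if ri[j] > 0.0]
    dropped = [names[j] for j in range(d) if ri[j] == 0.0]
    order = sorted(kept, key=lambda j: (-ri[j], j))
    return RankedList(
        method="mcfs",
        features=[names[j] for j in order],
        scores=[float(ri[j]) for j in order],
        meta={
            "c": params.c, "s": params.s, "m_proj": m,
            "u": params.u, "v": params.v,
            "train_fraction": params.train_fraction,
            "seed": params.seed, "dropped": dropped,
        },
    )


def rank_gbdt(X: FeatureMatrix, y, n_trees: int = 100, seed: int = 0) -> RankedList:
    """Split-count importance from a gradient-boosted tree ensemble."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    model = LGBMClassifier(
        n_estimators=n_trees,
        num_leaves=31,
        learning_rate=0.1,
        random_state=seed,
        deterministic=True,
        force_col_wise=True,
        n_jobs=1,
        verbose=-1,
    )
    model.fit(X.values, np.asarray(y))
    scores = model.booster_.feature_importance(importance_type="split").astype(float)
    feats, ordered_scores = _order_by_score(list(X.feature_names), scores)
    return RankedList(
        method="gbdt", features=feats, scores=ordered_scores,
        meta={"n_trees": n_trees, "num_leaves": 31,
              "learning_rate": 0.1, "seed": seed,
              "importance": "split_count"},
    )
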