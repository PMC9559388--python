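"""Incremental feature selection with oversampled cross-validation.

Nested prefixes of a ranked feature list are evaluated by stratified
k-fold cross-validation; within each fold the *training part only* is
rebalanced by SMOTE (synthetic minority points interpolated between
same-class nearest neighbors), a classifier (decision tree, random
forest, or RBF support-vector machine) is fit and the untouched test
part predicted.  Metrics are pooled over all out-of-fold predictions and
the prefix maximizing weighted F1 is declared optimal; a "feasible"
prefix is the smallest one within a tolerance of that maximum.

The multiclass Matthews correlation coefficient is computed in its
covariance form: with X and Y the one-hot true and predicted label
matrices, MCC = cov(X, Y) / sqrt(cov(X, X) cov(Y, Y)), the covariance
summed over class columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .types import FeatureMatrix, RankedList

CLASSIFIER_TAGS = ("dt", "rf", "svm")


# ---------------------------------------------------------------- SMOTE


def smote_balance(
    X_train: np.ndarray,
    y_train: np.ndarray | list,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Upsample every class to the majority count by interpolation.

    Each synthetic point is x + u * (x_nn - x) with u ~ Uniform(0, 1),
    x a uniformly chosen minority sample and x_nn one of its k nearest
    same-class neighbors (Euclidean).  Originals are kept unchanged and
    appear first in the output.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    classes, counts = np.unique(y_train, return_counts=True)
    if counts.min() < 2:
        bad = classes[counts.argmin()]
        raise ValueError(
            f"class {bad!r} has a single training sample; repair the "
            "stratification (larger folds or merged classes) before SMOTE"
        )
    majority = counts.max()
    if (counts == majority).all():
        return X_train, y_train

    rng = np.random.default_rng(seed)
    new_X = [X_train]
    new_y = [y_train]
    for cls, cnt in zip(classes, counts):
        deficit = int(majority - cnt)
        if deficit == 0:
            continue
        members = X_train[y_train == cls]
        k_eff = min(k_neighbors, cnt - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(members)
        # first neighbor is the point itself; drop it
        neighbor_idx = nn.kneighbors(members, return_distance=False)[:, 1:]
        base = rng.integers(0, cnt, size=deficit)
        pick = rng.integers(0, k_eff, size=deficit)
        u = rng.random(size=deficit)
        x = members[base]
        x_nn = members[neighbor_idx[base, pick]]
        new_X.append(x + u[:, None] * (x_nn - x))
        new_y.append(np.full(deficit, cls, dtype=y_train.dtype))
    return np.vstack(new_X), np.concatenate(new_y)


# -------------------------------------------------------------- metrics


@dataclass
class MetricsReport:
    per_class: dict[str, tuple[float, float, float]]  # precision, recall, f1
    acc: float
    mcc: float
    macro_f1: float
    weighted_f1: float
    support: dict[str, int]

    def row(self) -> dict[str, float]:
        out = {"acc": self.acc, "mcc": self.mcc,
               "macro_f1": self.macro_f1, "weighted_f1": self.weighted_f1}
        for cls, (_, _, f1) in self.per_class.items():
            out[f"f1_{cls}"] = f1
        return out


def _one_hot(labels: np.ndarray, classes: list) -> np.ndarray:
    pos = {c: j for j, c in enumerate(classes)}
    out = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        out[i, pos[lab]] = 1.0
    return out


def multiclass_mcc(y_true, y_pred, classes: list) -> float:
    """Covariance-form MCC over one-hot matrices; 0 when undefined."""
    X = _one_hot(np.asarray(y_true), classes)
    Y = _one_hot(np.asarray(y_pred), classes)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    cov_xy = float((Xc * Yc).sum())
    cov_xx = float((Xc * Xc).sum())
    cov_yy = float((Yc * Yc).sum())
    denom = np.sqrt(cov_xx) * np.sqrt(cov_yy)
    if denom == 0.0:
        return 0.0
    return cov_xy / denom


def compute_metrics(y_true, y_pred, classes: list) -> MetricsReport:
    """Per-class precision/recall/F1 (0/0 -> 0), ACC, covariance MCC,
    macro and support-weighted F1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    known = set(classes)
    if not set(y_pred) <= known or not set(y_true) <= known:
        raise ValueError("labels outside the declared class list")

    per_class: dict[str, tuple[float, float, float]] = {}
    support: dict[str, int] = {}
    f1s, weights = [], []
    for c in classes:
        tp = int(((y_true == c) & (y_pred == c)).sum())
        fp = int(((y_true != c) & (y_pred == c)).sum())
        fn = int(((y_true == c) & (y_pred != c)).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        per_class[c] = (precision, recall, f1)
        support[c] = int((y_true == c).sum())
        f1s.append(f1)
        weights.append(support[c])
    total = sum(weights)
    return MetricsReport(
        per_class=per_class,
        acc=float((y_true == y_pred).mean()),
        mcc=multiclass_mcc(y_true, y_pred, classes),
        macro_f1=float(np.mean(f1s)),
        weighted_f1=float(np.dot(f1s, weights) / total),
        support=support,
    )


# ------------------------------------------------------ cross-validation


def _make_classifier(tag: str, seed: int):
    if tag == "dt":
        return DecisionTreeClassifier(random_state=seed)
    if tag == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if tag == "svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    raise ValueError(f"unknown classifier tag {tag!r}; expected one of {CLASSIFIER_TAGS}")


def evaluate_prefix(
    X: FeatureMatrix,
    y,
    prefix_features: list[str],
    classifier: str = "svm",
    folds: int = 10,
    k_smote: int = 5,
    seed: int = 0,
) -> MetricsReport:
    """SMOTE-balanced stratified CV of one feature prefix; pooled metrics."""
    if not prefix_features:
        raise ValueError("prefix must be nonempty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.asarray(y)
    classes = sorted(set(y))
    values = X.subset(prefix_features).values
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof_pred = np.empty(len(y), dtype=y.dtype)
    for f, (tr, te) in enumerate(skf.split(values, y)):
        Xb, yb = smote_balance(values[tr], y[tr], k_neighbors=k_smote,
                               seed=seed + 1000 * (f + 1))
        model = _make_classifier(classifier, seed)
        model.fit(Xb, yb)
        oof_pred[te] = model.predict(values[te])
    return compute_metrics(y, oof_pred, classes)


@dataclass
class IFSResult:
    method: str
    classifier: str
    step: int
    rows: list[tuple[int, MetricsReport]]
    optimal_size: int
    optimal_metrics: MetricsReport
    feasible_size: int | None = None
    fold_seed: int = 0
    meta: dict = field(default_factory=dict)

    def curve(self) -> pd.DataFrame:
        records = []
        for size, rep in self.rows:
            rec = {"prefix_size": size}
            rec.update(rep.row())
            records.append(rec)
        return pd.DataFrame(records)

    def write_tsv(self, path: str | Path) -> None:
        self.curve().to_csv(path, sep="\t", index=False)

    def plot_curve(self, path: str | Path) -> None:
        """Weighted-F1 vs prefix size, with the optimum marked."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        sizes = [s for s, _ in self.rows]
        f1s = [r.weighted_f1 for _, r in self.rows]
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(sizes, f1s, marker="o", ms=3)
        ax.axvline(self.optimal_size, ls="--", lw=0.8, color="gray")
        ax.annotate(
            f"optimal: {self.optimal_size} "
            f"(wF1={self.optimal_metrics.weighted_f1:.4f})",
            xy=(self.optimal_size, self.optimal_metrics.weighted_f1),
            xytext=(5, -12), textcoords="offset points", fontsize=8,
        )
        ax.set_xlabel("number of top-ranked features")
        ax.set_ylabel("weighted F1")
        ax.set_title(f"{self.method} + {self.classifier}")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def run_ifs(
    X: FeatureMatrix,
    y,
    ranked: RankedList,
    classifier: str = "svm",
    step: int = 5,
    folds: int = 10,
    k_smote: int = 5,
    seed: int = 0,
    feasible_delta: float = 0.05,
) -> IFSResult:
    """Evaluate prefixes step, 2*step, ..., full list; pick the optimum.

    The optimal prefix is the smallest one attaining the maximum weighted
    F1 over the grid; the feasible prefix is the smallest within
    ``feasible_delta`` of that maximum.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if not ranked.features:
        raise ValueError("empty ranked list")
    total = len(ranked.features)
    sizes = list(range(step, total + 1, step))
    if not sizes or sizes[-1] != total:
        sizes.append(total)
    rows: list[tuple[int, MetricsReport]] = []
    for size in sizes:
        rep = evaluate_prefix(
            X, y, ranked.top(size), classifier=classifier,
            folds=folds, k_smote=k_smote, seed=seed,
        )
        rows.append((size, rep))
    best_f1 = max(rep.weighted_f1 for _, rep in rows)
    optimal_size, optimal_metrics = next(
        (s, r) for s, r in rows if r.weighted_f1 == best_f1
    )
    result = IFSResult(
        method=ranked.method,
        classifier=classifier,
        step=step,
        rows=rows,
        optimal_size=optimal_size,
        optimal_metrics=optimal_metrics,
        fold_seed=seed,
        meta={"folds": folds, "k_smote": k_smote},
    )
    result.feasible_size = select_feasible(result, delta=feasible_delta)
    return result


def select_feasible(result: IFSResult, delta: float = 0.05) -> int:
    """Smallest prefix whose weighted F1 is within delta of the maximum."""
    if not result.rows:
        raise ValueError("empty IFS result")
    best = max(rep.weighted_f1 for _, rep in result.rows)
    for size, rep in result.rows:
        if rep.weighted_f1 >= best - delta:
            return size
    return result.optimal_size  # unreachable; defensive
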