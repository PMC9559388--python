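"""Decision-rule extraction and cross-method feature reports.

A decision tree fit on the optimal features is unrolled into IF-THEN
rules, one per leaf: the conjunction of threshold predicates along the
root-to-leaf path, with redundant predicates on the same feature
collapsed to the tightest interval.  Companion reports summarize how the
feature sets chosen by different ranking methods intersect, and how a
feature set distributes over the three feature types.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .types import FEATURE_TYPES, FeatureMatrix


@dataclass
class Rule:
    predicates: list[tuple[str, str, float]]   # (feature, "<=" | ">", threshold)
    predicted_class: str
    support: int
    purity: float

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("rule support must be >= 1")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("rule purity must lie in (0, 1]")
        for _, cmp_, _ in self.predicates:
            if cmp_ not in ("<=", ">"):
                raise ValueError(f"unknown comparator {cmp_!r}")

    def matches(self, row: dict[str, float]) -> bool:
        for feat, cmp_, thr in self.predicates:
            v = row[feat]
            if cmp_ == "<=" and not v <= thr:
                return False
            if cmp_ == ">" and not v > thr:
                return False
        return True

    def text(self) -> str:
        if not self.predicates:
            cond = "TRUE"
        else:
            cond = " AND ".join(
                f"{feat} {cmp_} {thr:.6g}" for feat, cmp_, thr in self.predicates
            )
        return (f"IF {cond} THEN {self.predicted_class} "
                f"(support={self.support}, purity={self.purity:.3f})")


@dataclass
class RuleSet:
    rules: list[Rule]
    features: list[str]
    classes: list[str]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rules)

    def predict_row(self, row: dict[str, float]) -> str:
        for rule in self.rules:
            if rule.matches(row):
                return rule.predicted_class
        raise ValueError("no rule matched; rule set is not a partition")

    def predict(self, X: FeatureMatrix) -> np.ndarray:
        df = X.to_frame()
        return np.asarray(
            [self.predict_row(dict(zip(df.columns, r))) for r in df.to_numpy()]
        )

    def write_text(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(r.text() for r in self.rules) + "\n")

    def write_json(self, path: str | Path) -> None:
        payload = [
            {
                "predicates": [
                    {"feature": f, "comparator": c, "threshold": t}
                    for f, c, t in r.predicates
                ],
                "class": r.predicted_class,
                "support": r.support,
                "purity": r.purity,
            }
            for r in self.rules
        ]
        Path(path).write_text(json.dumps(payload, indent=2))


def extract_rules(
    X: FeatureMatrix,
    y,
    optimal_features: list[str],
    seed: int = 0,
    max_depth: int | None = None,
) -> RuleSet:
    """One rule per leaf of a tree fit on all samples.

    Each rule's support is the number of training samples reaching the
    leaf; purity is the majority-class fraction there.
    """
    missing = set(optimal_features) - set(X.feature_names)
    if missing:
        raise ValueError(f"features not in matrix: {sorted(missing)}")
    y = np.asarray(y)
    sub = X.subset(optimal_features)
    tree = DecisionTreeClassifier(random_state=seed, max_depth=max_depth)
    tree.fit(sub.values, y)
    t = tree.tree_
    class_names = [str(c) for c in tree.classes_]

    rules: list[Rule] = []

    def walk(node: int, bounds: dict[str, list[float | None]],
             order: list[str]) -> None:
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            counts = t.value[node][0]
            total = counts.sum()
            best = int(counts.argmax())
            predicates = []
            for feat in order:
                lo, hi = bounds[feat]
                if hi is not None:
                    predicates.append((feat, "<=", hi))
                if lo is not None:
                    predicates.append((feat, ">", lo))
            rules.append(
                Rule(
                    predicates=predicates,
                    predicted_class=class_names[best],
                    support=int(t.n_node_samples[node]),
                    purity=float(counts[best] / total),
                )
            )
            return
        feat = optimal_features[int(t.feature[node])]
        thr = float(t.threshold[node])
        if feat not in bounds:
            bounds[feat] = [None, None]
            order.append(feat)
            added = True
        else:
            added = False
        lo, hi = bounds[feat]
        # left branch: feat <= thr (tightest upper bound = min)
        bounds[feat] = [lo, thr if hi is None else min(hi, thr)]
        walk(left, bounds, order)
        # right branch: feat > thr (tightest lower bound = max)
        bounds[feat] = [thr if lo is None else max(lo, thr), hi]
        walk(right, bounds, order)
        bounds[feat] = [lo, hi]
        if added:
            order.pop()
            del bounds[feat]

    walk(0, {}, [])
    return RuleSet(
        rules=rules,
        features=list(optimal_features),
        classes=sorted(set(str(c) for c in y)),
        meta={"seed": seed, "max_depth": max_depth, "n_leaves": len(rules)},
    )


def rules_per_class(ruleset: RuleSet) -> dict[str, int]:
    """Rule counts by predicted class; classes with no rule map to 0."""
    counts = {c: 0 for c in ruleset.classes}
    for rule in ruleset.rules:
        counts[rule.predicted_class] = counts.get(rule.predicted_class, 0) + 1
    return counts


@dataclass
class IntersectionReport:
    membership: dict[str, set[str]]        # feature -> methods containing it
    tiers: dict[int, set[str]]             # k -> features in exactly k sets
    core: set[str]                         # features in every set

    def to_json(self) -> str:
        return json.dumps(
            {
                "membership": {f: sorted(m) for f, m in sorted(self.membership.items())},
                "tiers": {str(k): sorted(v) for k, v in sorted(self.tiers.items())},
                "core": sorted(self.core),
            },
            indent=2,
        )


def intersect_feature_sets(named_sets: dict[str, set[str]]) -> IntersectionReport:
    """Exact membership tiers over >= 2 named feature sets."""
    if len(named_sets) < 2:
        raise ValueError("need at least 2 feature sets")
    membership: dict[str, set[str]] = {}
    for method, feats in named_sets.items():
        for f in feats:
            membership.setdefault(f, set()).add(method)
    n_sets = len(named_sets)
    tiers: dict[int, set[str]] = {k: set() for k in range(1, n_sets + 1)}
    for f, methods in membership.items():
        tiers[len(methods)].add(f)
    return IntersectionReport(
        membership=membership, tiers=tiers, core=tiers[n_sets]
    )


def feature_type_breakdown(
    features: list[str], feature_types: dict[str, str]
) -> dict[str, int]:
    """Counts of a feature list by type tag (enrichment | text | network)."""
    counts = {t: 0 for t in FEATURE_TYPES}
    for f in features:
        tag = feature_types[f]
        if tag not in counts:
            raise ValueError(f"unknown feature type {tag!r} for {f!r}")
        counts[tag] += 1
    return counts
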