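"""All-relevant feature screening with shadow features.

Each iteration appends an independently permuted copy ("shadow") of every
candidate column, fits a random-forest importance estimator on the
doubled matrix, and credits a *hit* to every original feature whose
importance beats the best shadow.  A feature whose hit count is
binomially improbable under the fair-coin null (Bonferroni-corrected over
the still-undecided features) is accepted (too many hits) or rejected
(too few); survivors at the iteration cap stay tentative.

Rejected features are removed from subsequent model fits; this sharpens
the importance signal of the remaining candidates without changing the
hit semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier

from .types import FeatureMatrix


@dataclass
class ScreeningResult:
    accepted: set[str]
    tentative: set[str]
    rejected: set[str]
    hit_counts: dict[str, int]
    n_iterations: int
    alpha: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [self.accepted, self.tentative, self.rejected]
        total = sum(len(s) for s in sets)
        if len(self.accepted | self.tentative | self.rejected) != total:
            raise ValueError("accepted/tentative/rejected must be disjoint")
        if any(h > self.n_iterations for h in self.hit_counts.values()):
            raise ValueError("hit count exceeds iteration count")

    def retained(self, include_tentative: bool = False) -> set[str]:
        return self.accepted | (self.tentative if include_tentative else set())


def boruta_screen(
    X: FeatureMatrix,
    y: np.ndarray | list,
    max_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    n_estimators: int = 200,
) -> ScreeningResult:
    """Partition features into accepted / tentative / rejected."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("screening requires at least 2 classes")
    if X.shape[0] < 10:
        raise ValueError("screening requires at least 10 samples")
    if max_iter < 10:
        raise ValueError("max_iter must be at least 10")

    names = list(X.feature_names)
    values = X.values
    spread = values.max(axis=0) - values.min(axis=0)
    zero_var = [names[j] for j in np.flatnonzero(spread == 0.0)]
    if zero_var:
        warnings.warn(
            f"{len(zero_var)} zero-variance feature(s) auto-rejected",
            stacklevel=2,
        )
    active = [j for j in range(len(names)) if spread[j] > 0.0]

    rng = np.random.default_rng(seed)
    hits = {name: 0 for name in names}
    accepted: set[str] = set()
    rejected: set[str] = set(zero_var)
    undecided = {names[j] for j in active}
    n_samples = values.shape[0]
    iterations = 0

    for t in range(1, max_iter + 1):
        if not undecided:
            break
        iterations = t
        cols = [j for j in active if names[j] not in rejected]
        orig = values[:, cols]
        shadow = np.empty_like(orig)
        for k in range(orig.shape[1]):
            shadow[:, k] = orig[rng.permutation(n_samples), k]
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(np.hstack([orig, shadow]), y)
        imp = forest.feature_importances_
        orig_imp, shadow_imp = imp[: len(cols)], imp[len(cols):]
        threshold = shadow_imp.max()
        for k, j in enumerate(cols):
            if names[j] in undecided and orig_imp[k] > threshold:
                hits[names[j]] += 1

        corrected = alpha / len(undecided)
        for name in sorted(undecided):
            h = hits[name]
            if binom.sf(h - 1, t, 0.5) < corrected:       # P(X >= h)
                accepted.add(name)
                undecided.discard(name)
            elif binom.cdf(h, t, 0.5) < corrected:        # P(X <= h)
                rejected.add(name)
                undecided.discard(name)

    return ScreeningResult(
        accepted=accepted,
        tentative=set(undecided),
        rejected=rejected,
        hit_counts=hits,
        n_iterations=iterations,
        alpha=alpha,
        meta={"seed": seed, "max_iter": max_iter, "n_estimators": n_estimators},
    )
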