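"""Ranker contracts: oracle equivalence, recovery, tie-breaking."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from mutclass import (
    FeatureMatrix,
    MCFSParams,
    rank_gbdt,
    rank_lasso,
    rank_mcfs,
    rank_mrmr,
)
from mutclass.ranking import discretize_three_state
from conftest import make_informative_matrix


def _matrix(values: np.ndarray, names: list[str]) -> FeatureMatrix:
    return FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        feature_names=names,
        feature_types=["enrichment"] * len(names),
        values=values,
    )


# ------------------------------------------------------------------ lasso


def test_lasso_puts_class_indicator_first():
    rng = np.random.default_rng(0)
    n = 300
    y = rng.integers(0, 2, size=n)
    values = np.column_stack(
        [y + rng.normal(scale=0.01, size=n)] +
        [rng.normal(size=n) for _ in range(10)]
    )
    fm = _matrix(values, ["ind"] + [f"z{j}" for j in range(10)])
    ranked = rank_lasso(fm, [f"C{c}" for c in y], seed=1)
    assert ranked.features[0] == "ind"
    assert sorted(ranked.features) == sorted(fm.feature_names)


def test_lasso_constant_feature_scores_zero_and_goes_last():
    rng = np.random.default_rng(1)
    n = 100
    y = rng.integers(0, 2, size=n)
    values = np.column_stack([
        y + rng.normal(scale=0.1, size=n),
        np.full(n, 7.0),
    ])
    fm = _matrix(values, ["good", "const"])
    ranked = rank_lasso(fm, [f"C{c}" for c in y], seed=0)
    assert ranked.features[-1] == "const"
    assert ranked.scores[-1] == 0.0
    assert ranked.scores == sorted(ranked.scores, reverse=True)


# ------------------------------------------------------------------ mRMR


def brute_mi(a, b) -> float:
    """Independent MI oracle from joint frequencies, in nats."""
    n = len(a)
    joint = Counter(zip(a, b))
    pa, pb = Counter(a), Counter(b)
    mi = 0.0
    for (x, z), c in joint.items():
        pxy = c / n
        mi += pxy * math.log(pxy / (pa[x] / n * pb[z] / n))
    return mi


def brute_mrmr(disc: np.ndarray, y, n_select: int) -> list[int]:
    """Exhaustive greedy recomputation (difference form)."""
    d = disc.shape[1]
    rel = [brute_mi(disc[:, j], list(y)) for j in range(d)]
    selected: list[int] = []
    remaining = list(range(d))
    while len(selected) < n_select:
        best, best_val = None, -math.inf
        for j in remaining:
            red = (sum(brute_mi(disc[:, j], disc[:, s]) for s in selected)
                   / len(selected)) if selected else 0.0
            val = rel[j] - red
            if val > best_val + 1e-12:
                best, best_val = j, val
        selected.append(best)
        remaining.remove(best)
    return selected


def test_mrmr_first_pick_maximizes_relevance():
    fm, y = make_informative_matrix(150, 5, 10, 3, seed=11)
    disc = discretize_three_state(fm.values)
    rel = [brute_mi(disc[:, j], list(y)) for j in range(disc.shape[1])]
    ranked = rank_mrmr(fm, y)
    assert ranked.features[0] == fm.feature_names[int(np.argmax(rel))]


def test_mrmr_trajectory_equals_bruteforce():
    for seed in (0, 1, 2):
        fm, y = make_informative_matrix(150, 4, 8, 3, seed=seed)
        disc = discretize_three_state(fm.values)
        expected = brute_mrmr(disc, y, 12)
        ranked = rank_mrmr(fm, y)
        assert ranked.features == [fm.feature_names[j] for j in expected]


def test_mrmr_duplicate_of_first_pick_not_second():
    rng = np.random.default_rng(4)
    n = 200
    y = rng.integers(0, 2, size=n)
    strong = y + rng.normal(scale=0.2, size=n)
    weak = y + rng.normal(scale=2.0, size=n)
    values = np.column_stack([strong, strong.copy(), weak])
    fm = _matrix(values, ["strong", "strong_dup", "weak"])
    ranked = rank_mrmr(fm, [f"C{c}" for c in y])
    assert ranked.features[0] == "strong"
    assert ranked.features[1] == "weak"


def test_mrmr_rejects_bad_n_select(small_enrichment):
    with pytest.raises(ValueError):
        rank_mrmr(small_enrichment, ["A"] * small_enrichment.shape[0], n_select=0)


# ------------------------------------------------------------------ MCFS


def test_mcfs_informative_feature_tops_ranking():
    wins = 0
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        n = 200
        y = rng.integers(0, 2, size=n)
        values = np.column_stack(
            [y + rng.normal(scale=0.1, size=n)] +
            [rng.normal(size=n) for _ in range(20)]
        )
        fm = _matrix(values, ["inf"] + [f"z{j}" for j in range(20)])
        ranked = rank_mcfs(fm, [f"C{c}" for c in y],
                           MCFSParams(c=20, s=50, m_proj=5, seed=seed))
        if ranked.features and ranked.features[0] == "inf":
            wins += 1
    assert wins >= 4


def test_mcfs_scores_nonnegative_sorted_and_zero_dropped(small_enrichment, small_study):
    y = small_study.cohort.labels
    ranked = rank_mcfs(small_enrichment, y, MCFSParams(c=5, s=10, m_proj=3, seed=0))
    assert all(s > 0 for s in ranked.scores)
    assert ranked.scores == sorted(ranked.scores, reverse=True)
    assert set(ranked.features) | set(ranked.meta["dropped"]) == \
        set(small_enrichment.feature_names)


def test_mcfs_m_proj_too_large():
    fm, y = make_informative_matrix(60, 2, 2, 2, seed=0)
    with pytest.raises(ValueError):
        rank_mcfs(fm, y, MCFSParams(m_proj=10))


# ------------------------------------------------------------------ GBDT


def test_gbdt_split_counts_conserved_and_unused_zero():
    fm, y = make_informative_matrix(200, 3, 10, 3, seed=21, shift=3.0)
    ranked = rank_gbdt(fm, y, n_trees=30, seed=2)
    assert sorted(ranked.features) == sorted(fm.feature_names)
    assert all(s >= 0 for s in ranked.scores)
    # recompute total split count from the booster directly
    from lightgbm import LGBMClassifier

    model = LGBMClassifier(n_estimators=30, num_leaves=31, learning_rate=0.1,
                           random_state=2, deterministic=True,
                           force_col_wise=True, n_jobs=1, verbose=-1)
    model.fit(fm.values, y)
    total = model.booster_.feature_importance(importance_type="split").sum()
    assert sum(ranked.scores) == total


def test_gbdt_determinism(small_enrichment, small_study):
    y = small_study.cohort.labels
    r1 = rank_gbdt(small_enrichment, y, seed=5)
    r2 = rank_gbdt(small_enrichment, y, seed=5)
    assert r1.features == r2.features and r1.scores == r2.scores


# ------------------------------------------------------- cross-method


def test_four_lists_are_permutations_and_differ(small_study, small_enrichment):
    from scipy.stats import kendalltau

    y = small_study.cohort.labels
    fm = small_enrichment
    lists = {
        "lasso": rank_lasso(fm, y, seed=1),
        "mrmr": rank_mrmr(fm, y),
        "mcfs": rank_mcfs(fm, y, MCFSParams(c=10, s=30, m_proj=4, seed=1)),
        "gbdt": rank_gbdt(fm, y, seed=1),
    }
    for r in lists.values():
        assert len(set(r.features)) == len(r.features)
        assert set(r.features) <= set(fm.feature_names)
    # pairwise: no two full lists are identical orderings
    common = set.intersection(*(set(r.features) for r in lists.values()))
    names = sorted(lists)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ra = [f for f in lists[a].features if f in common]
            rb = [f for f in lists[b].features if f in common]
            pos = {f: k for k, f in enumerate(rb)}
            tau, _ = kendalltau(range(len(ra)), [pos[f] for f in ra])
            assert tau < 1.0
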