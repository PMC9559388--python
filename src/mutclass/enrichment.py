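"""Per-sample gene-set enrichment features.

A sample's relationship to an annotation term is scored as the -log10 of
the hypergeometric upper-tail probability of the observed overlap between
the sample's mutated genes and the term's gene set: with a universe of N
genes, a term of M genes and a sample of n mutated genes sharing m with
the term,

    score = -log10  sum_{k=m}^{min(n,M)}  C(M,k) C(N-M,n-k) / C(N,n).

Large scores mean the sample's mutations concentrate in the term far more
than chance.  All tail sums are evaluated in log space via log-gamma with
log-sum-exp, so deep tails never underflow; scores are capped (default
300, i.e. p ~ 1e-300) to keep downstream learners finite.
"""

from __future__ import annotations

import warnings
from functools import lru_cache
from math import exp, inf, lgamma, log1p

import numpy as np

from .types import AnnotationCatalog, Cohort, FeatureMatrix, MutationProfile

DEFAULT_SCORE_CAP = 300.0

_LN10 = np.log(10.0)


def _check_counts(N: int, M: int, n: int, m: int) -> None:
    if N < 0:
        raise ValueError(f"N must be nonnegative, got N={N}")
    if not (0 <= M <= N):
        raise ValueError(f"M must satisfy 0 <= M <= N, got M={M}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"n must satisfy 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= m <= min(n, M)):
        raise ValueError(
            f"m must satisfy 0 <= m <= min(n, M), got m={m}, n={n}, M={M}"
        )


@lru_cache(maxsize=200_000)
def _log10_tail_table(N: int, M: int, n: int) -> tuple[float, ...]:
    """log10 P(X >= m) for every m in 0..min(n, M).

    X is hypergeometric(N, M, n); its support is k in
    [max(0, n - (N - M)), min(n, M)].  The table is built once per
    (N, M, n) via a reverse log-sum-exp over the log pmf.
    """
    kmax = min(n, M)
    kmin = max(0, n - (N - M))
    const = (
        lgamma(M + 1) + lgamma(N - M + 1)
        - (lgamma(N + 1) - lgamma(n + 1) - lgamma(N - n + 1))
    )
    log_pmf = [
        const - lgamma(k + 1) - lgamma(M - k + 1)
        - lgamma(n - k + 1) - lgamma(N - M - n + k + 1)
        for k in range(kmin, kmax + 1)
    ]
    # small tails: suffix log-sum-exp, exact in log space
    suffix = [0.0] * len(log_pmf)
    acc = -inf
    for i in range(len(log_pmf) - 1, -1, -1):
        a, b = log_pmf[i], acc
        if a < b:
            a, b = b, a
        acc = a if b == -inf else a + log1p(exp(b - a))
        suffix[i] = acc
    # large tails (head mass < 1/2): log1p of the complementary head sum,
    # which keeps full relative accuracy when the tail is close to 1
    out = [0.0] * (kmax + 1)
    head = 0.0
    for i, m in enumerate(range(kmin, kmax + 1)):
        if head < 0.5:
            v = log1p(-head) / _LN10
        else:
            v = suffix[i] / _LN10
        out[m] = min(v, 0.0)
        head += exp(log_pmf[i])
    # below the support's lower edge (m < kmin) the tail is 1, log10 = 0
    return tuple(out)


def log10_hypergeom_tail(N: int, M: int, n: int, m: int) -> float:
    """log10 of the hypergeometric upper tail P(X >= m); always <= 0."""
    _check_counts(N, M, n, m)
    if m == 0:
        return 0.0
    return _log10_tail_table(N, M, n)[m]


def enrichment_score(
    profile: MutationProfile,
    term_id: str,
    catalog: AnnotationCatalog,
    score_cap: float = DEFAULT_SCORE_CAP,
) -> float:
    """-log10 tail probability of the sample/term overlap, capped.

    Genes outside the catalog universe are dropped before counting.  A
    zero overlap scores exactly 0; an empty in-universe gene set warns
    and scores 0 for every term.
    """
    term_genes = catalog.term_genes(term_id)  # raises KeyError if unknown
    universe = set(catalog.universe)
    in_universe = profile.genes & universe
    n = len(in_universe)
    if n == 0:
        warnings.warn(
            f"sample {profile.sample_id!r} has no genes in the universe; "
            "all enrichment scores are 0",
            stacklevel=2,
        )
        return 0.0
    m = len(in_universe & term_genes)
    if m == 0:
        return 0.0
    tail = log10_hypergeom_tail(len(catalog.universe), len(term_genes), n, m)
    return min(-tail, score_cap)


def encode_cohort_enrichment(
    cohort: Cohort,
    catalog: AnnotationCatalog,
    score_cap: float = DEFAULT_SCORE_CAP,
) -> FeatureMatrix:
    """Samples x terms enrichment matrix, columns in catalog term order."""
    if set(cohort.universe) != set(catalog.universe):
        raise ValueError("cohort and catalog universes differ")
    gene_pos = {g: i for i, g in enumerate(catalog.universe)}
    N = len(catalog.universe)
    term_ids = catalog.term_ids
    term_masks = np.zeros((len(term_ids), N), dtype=bool)
    for j, tid in enumerate(term_ids):
        for g in catalog.term_genes(tid):
            term_masks[j, gene_pos[g]] = True
    term_sizes = term_masks.sum(axis=1)

    values = np.zeros((len(cohort), len(term_ids)))
    for i, prof in enumerate(cohort.profiles):
        idx = [gene_pos[g] for g in prof.genes if g in gene_pos]
        n = len(idx)
        if n == 0:
            warnings.warn(
                f"sample {prof.sample_id!r} has no genes in the universe",
                stacklevel=2,
            )
            continue
        overlaps = term_masks[:, idx].sum(axis=1)
        for j, (M, m) in enumerate(zip(term_sizes, overlaps)):
            if m == 0:
                continue
            tail = _log10_tail_table(N, int(M), n)[int(m)]
            values[i, j] = min(-tail, score_cap)
    return FeatureMatrix(
        sample_ids=cohort.sample_ids,
        feature_names=list(term_ids),
        feature_types=["enrichment"] * len(term_ids),
        values=values,
    )
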