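"""Synthetic cohorts with planted class-specific driver pathways.

The generator emulates the statistical structure a mutation-profile
classifier relies on: each tumor class preferentially mutates the genes of
a few "driver" gene sets, per-sample mutation burden is heterogeneous
(negative-binomial), class sizes are imbalanced, and the gene-interaction
graph has communities aligned with the annotation catalog's gene sets.
Ground-truth driver assignments are recorded so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import WeightedGraph
from .types import AnnotationCatalog, Cohort, MutationProfile

#: Class sizes of a published 11-type pan-cancer mutation cohort
#: (BLCA ... UCEC, 3478 samples in total); useful as an imbalance shape.
PANCANCER_CLASS_SIZES = (100, 513, 499, 276, 306, 473, 201, 230, 177, 456, 247)

_MIN_BURDEN = 3  # floor on mutations per sample

# weight range for interaction-confidence scores
_W_LO, _W_HI = 0.15, 0.999


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults describe the reference desk-scale cohort used throughout the
    test-suite: 2,000 genes, 150 annotation terms, six imbalanced tumor
    classes of 600 samples in total, one driver term per class, and
    half of each sample's mutations drawn from its class's driver genes.
    """

    n_genes: int = 2000
    n_terms: int = 150
    term_size_range: tuple[int, int] = (10, 200)
    n_classes: int = 6
    drivers_per_class: int = 1
    class_sizes: tuple[int, ...] = (160, 60, 140, 80, 100, 60)
    signal_fraction: float = 0.5
    burden_mean: float = 60.0
    burden_dispersion: float = 2.0
    edge_prob_within_term: float = 0.1
    edge_prob_background: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi):
            raise ValueError("term_size_range must satisfy 1 <= min <= max")
        if hi > self.n_genes:
            raise ValueError("term_size_range.max exceeds n_genes")
        if self.drivers_per_class > self.n_terms:
            raise ValueError("drivers_per_class exceeds n_terms")
        if len(self.class_sizes) != self.n_classes:
            raise ValueError("class_sizes length must equal n_classes")
        if any(s < 2 for s in self.class_sizes):
            raise ValueError("every class needs at least 2 samples")
        if not (0.0 <= self.signal_fraction <= 1.0):
            raise ValueError("signal_fraction must lie in [0, 1]")
        if self.burden_mean <= 0 or self.burden_dispersion <= 0:
            raise ValueError("burden parameters must be positive")
        for p in (self.edge_prob_within_term, self.edge_prob_background):
            if not (0.0 <= p <= 1.0):
                raise ValueError("edge probabilities must lie in [0, 1]")

    @property
    def universe(self) -> list[str]:
        return [f"G{i:06d}" for i in range(self.n_genes)]

    @property
    def class_names(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_classes)]


def build_annotation_catalog(spec: SyntheticSpec) -> AnnotationCatalog:
    """Draw ``n_terms`` gene sets, sizes uniform on ``term_size_range``.

    Term ids alternate between GO-like and KEGG-like namespaces purely for
    realism of downstream reports; membership is sampled without
    replacement from the universe.
    """
    rng = np.random.default_rng(spec.seed)
    universe = spec.universe
    lo, hi = spec.term_size_range
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for j in range(spec.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(spec.n_genes, size=size, replace=False)
        ns = "GO" if j % 2 == 0 else "KEGG"
        prefix = "GO:" if ns == "GO" else "hsa"
        tid = f"{prefix}{j:05d}"
        terms[tid] = (ns, frozenset(universe[i] for i in members))
    return AnnotationCatalog(universe=universe, terms=terms)


def _assign_drivers(
    spec: SyntheticSpec, term_ids: list[str], rng: np.random.Generator
) -> dict[str, list[str]]:
    need = spec.drivers_per_class * spec.n_classes
    if need <= spec.n_terms:
        picks = rng.choice(len(term_ids), size=need, replace=False)
        return {
            cls: [term_ids[i] for i in picks[k * spec.drivers_per_class:
                                             (k + 1) * spec.drivers_per_class]]
            for k, cls in enumerate(spec.class_names)
        }
    # not enough terms for disjoint assignment: sample per class independently
    return {
        cls: [term_ids[i] for i in
              rng.choice(len(term_ids), size=spec.drivers_per_class, replace=False)]
        for cls in spec.class_names
    }


def simulate_cohort(spec: SyntheticSpec, catalog: AnnotationCatalog) -> Cohort:
    """Simulate mutation profiles with class-specific driver enrichment.

    Per sample, a mutation count is drawn from a negative binomial with
    mean ``burden_mean`` and dispersion ``burden_dispersion`` (floored at
    3); a ``signal_fraction`` share of the draws is uniform over the
    union of the class's driver gene sets, the rest uniform over the
    universe.  Duplicate draws collapse to a set.
    """
    if catalog.universe != spec.universe:
        raise ValueError("catalog universe does not match spec universe")
    rng = np.random.default_rng(spec.seed + 1)
    universe = np.asarray(spec.universe, dtype=object)
    gene_pos = {g: i for i, g in enumerate(spec.universe)}
    truth = _assign_drivers(spec, catalog.term_ids, rng)

    driver_pool: dict[str, np.ndarray] = {}
    for cls, tids in truth.items():
        union: set[str] = set()
        for t in tids:
            union |= catalog.term_genes(t)
        if not union:
            raise ValueError(f"class {cls!r} has an empty driver union")
        driver_pool[cls] = np.asarray(sorted(gene_pos[g] for g in union))

    # negative binomial parameterized by mean/dispersion:
    # r = dispersion, p = r / (r + mean)
    r = spec.burden_dispersion
    p_nb = r / (r + spec.burden_mean)

    profiles: list[MutationProfile] = []
    sid = 0
    for cls, size in zip(spec.class_names, spec.class_sizes):
        pool = driver_pool[cls]
        for _ in range(size):
            count = max(int(rng.negative_binomial(r, p_nb)), _MIN_BURDEN)
            n_signal = int(rng.binomial(count, spec.signal_fraction))
            draws = []
            if n_signal:
                draws.append(rng.choice(pool, size=n_signal, replace=True))
            if count - n_signal:
                draws.append(
                    rng.integers(0, spec.n_genes, size=count - n_signal)
                )
            idx = np.unique(np.concatenate(draws))
            profiles.append(
                MutationProfile(
                    sample_id=f"S{sid:05d}",
                    class_label=cls,
                    genes=frozenset(universe[idx]),
                )
            )
            sid += 1
    return Cohort(
        profiles=profiles,
        universe=spec.universe,
        classes=spec.class_names,
        truth={c: list(t) for c, t in truth.items()},
    )


def build_interaction_graph(
    spec: SyntheticSpec, catalog: AnnotationCatalog
) -> WeightedGraph:
    """Interaction graph whose communities align with catalog gene sets.

    Every unordered gene pair co-occurring in at least one term gains an
    edge with probability ``edge_prob_within_term``; all remaining pairs
    with probability ``edge_prob_background``.  Weights are Beta(2, 2)
    rescaled into (0.15, 0.999], mimicking interaction-confidence scores.
    """
    rng = np.random.default_rng(spec.seed + 2)
    gene_pos = {g: i for i, g in enumerate(spec.universe)}
    n = spec.n_genes

    within: set[tuple[int, int]] = set()
    for tid in catalog.term_ids:
        idx = sorted(gene_pos[g] for g in catalog.term_genes(tid))
        k = len(idx)
        for a in range(k):
            ia = idx[a]
            for b in range(a + 1, k):
                within.add((ia, idx[b]))

    edge_pairs: list[tuple[int, int]] = []
    if within and spec.edge_prob_within_term > 0:
        pairs = sorted(within)
        keep = rng.random(len(pairs)) < spec.edge_prob_within_term
        edge_pairs.extend(p for p, k in zip(pairs, keep) if k)

    # background edges: sample the binomial count of edges among the
    # non-within pairs, then draw distinct pairs by rejection
    total_pairs = n * (n - 1) // 2
    n_other = total_pairs - len(within)
    if n_other > 0 and spec.edge_prob_background > 0:
        n_bg = int(rng.binomial(n_other, spec.edge_prob_background))
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < n_bg:
            need = n_bg - len(chosen)
            a = rng.integers(0, n, size=2 * need + 8)
            b = rng.integers(0, n, size=2 * need + 8)
            for ia, ib in zip(a, b):
                if ia == ib:
                    continue
                key = (min(ia, ib), max(ia, ib))
                if key in within or key in chosen:
                    continue
                chosen.add((int(key[0]), int(key[1])))
                if len(chosen) == n_bg:
                    break
        edge_pairs.extend(sorted(chosen))

    edge_pairs.sort()
    weights = _W_LO + (_W_HI - _W_LO) * rng.beta(2.0, 2.0, size=len(edge_pairs))
    # Beta(2,2) can hit exactly 0; nudge onto the open interval
    weights = np.clip(weights, np.nextafter(_W_LO, 1.0), _W_HI)
    edges = [
        (spec.universe[a], spec.universe[b], float(w))
        for (a, b), w in zip(edge_pairs, weights)
    ]
    return WeightedGraph(nodes=list(spec.universe), edges=edges)


@dataclass
class SyntheticStudy:
    """Convenience bundle: catalog + cohort + graph from one spec."""

    spec: SyntheticSpec
    catalog: AnnotationCatalog = field(init=False)
    cohort: Cohort = field(init=False)
    graph: WeightedGraph = field(init=False)

    def __post_init__(self) -> None:
        self.catalog = build_annotation_catalog(self.spec)
        self.cohort = simulate_cohort(self.spec, self.catalog)
        self.graph = build_interaction_graph(self.spec, self.catalog)
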