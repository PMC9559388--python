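"""Text features: gene-sentence embeddings averaged per sample.

Each sample's mutated genes form one "sentence" (gene symbols as words,
order randomized, since a mutation set has no natural order); skip-gram
training over the cohort corpus places genes that are co-mutated across
samples near each other.  A sample's feature vector is the arithmetic
mean of its genes' vectors — 256 dimensions by default.
"""

from __future__ import annotations

import warnings

import numpy as np

from .embeddings import EmbeddingTable, mean_pool, train_skipgram
from .types import Cohort, FeatureMatrix

DEFAULT_TEXT_DIM = 256


def build_corpus(cohort: Cohort, seed: int) -> list[list[str]]:
    """One sentence per sample: its genes in a seeded uniform shuffle."""
    if not cohort.profiles:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    corpus = []
    for prof in cohort.profiles:
        genes = sorted(prof.genes)
        rng.shuffle(genes)
        corpus.append(genes)
    return corpus


def train_gene_embeddings(
    corpus: list[list[str]],
    dim: int = DEFAULT_TEXT_DIM,
    window: int = 10,
    epochs: int = 10,
    min_count: int = 1,
    seed: int = 0,
) -> EmbeddingTable:
    return train_skipgram(
        corpus, dim=dim, window=window, epochs=epochs,
        min_count=min_count, seed=seed,
    )


def embed_samples_text(cohort: Cohort, table: EmbeddingTable) -> FeatureMatrix:
    """Mean gene vector per sample; width = table.dim for every sample."""
    pooled, missing = mean_pool([p.genes for p in cohort.profiles], table)
    for i in missing:
        warnings.warn(
            f"sample {cohort.profiles[i].sample_id!r} has no genes in the "
            "embedding table; text features are zero",
            stacklevel=2,
        )
    width = int(np.ceil(np.log10(max(table.dim, 2))))
    names = [f"txt_{i:0{max(width, 3)}d}" for i in range(table.dim)]
    return FeatureMatrix(
        sample_ids=cohort.sample_ids,
        feature_names=names,
        feature_types=["text"] * table.dim,
        values=pooled,
    )
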