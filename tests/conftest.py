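"""Shared fixtures.

The small synthetic study is sized for fast unit tests; the full-scale
pipeline run (600 samples, 2,000 genes, 150 terms) is session-scoped and
shared by the end-to-end assertions so the expensive computation happens
once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from mutclass import (
    FeatureMatrix,
    PipelineConfig,
    SyntheticSpec,
    SyntheticStudy,
    encode_cohort_enrichment,
    run_pipeline,
)


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    return SyntheticSpec(
        n_genes=300,
        n_terms=20,
        term_size_range=(8, 30),
        n_classes=3,
        drivers_per_class=2,
        class_sizes=(40, 25, 35),
        signal_fraction=0.6,
        burden_mean=25,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_spec) -> SyntheticStudy:
    return SyntheticStudy(small_spec)


@pytest.fixture(scope="session")
def small_enrichment(small_study) -> FeatureMatrix:
    return encode_cohort_enrichment(small_study.cohort, small_study.catalog)


@pytest.fixture(scope="session")
def full_pipeline_result():
    """Full-scale reference study: 6 classes, 600 samples, 2,000 genes,
    150 terms, signal fraction 0.5, 32-dim embeddings."""
    return run_pipeline(PipelineConfig(seed=1))


def make_informative_matrix(
    n: int,
    n_informative: int,
    n_noise: int,
    n_classes: int,
    seed: int,
    shift: float = 2.0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Gaussian features; informative columns are class-mean shifted."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, n_classes, size=n)
    cols = []
    for j in range(n_informative):
        means = rng.normal(0.0, shift, size=n_classes)
        cols.append(means[y] + rng.normal(size=n))
    for j in range(n_noise):
        cols.append(rng.normal(size=n))
    values = np.column_stack(cols)
    names = [f"inf_{j:03d}" for j in range(n_informative)] + [
        f"noise_{j:03d}" for j in range(n_noise)
    ]
    fm = FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        feature_names=names,
        feature_types=["enrichment"] * len(names),
        values=values,
    )
    return fm, np.asarray([f"C{c}" for c in y])
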