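"""Core data containers shared across the pipeline.

A cohort is a collection of per-sample mutated-gene sets with class labels
(tumor types), defined over an explicit gene universe.  An annotation
catalog holds named gene sets (GO-like terms and KEGG-like pathways) over
the same universe.  Feature matrices carry type-tagged per-sample features
(enrichment | text | network) and are the common currency of the screening,
ranking and selection stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FEATURE_TYPES = ("enrichment", "text", "network")


@dataclass(frozen=True)
class MutationProfile:
    """One sample: identifier, class label and its set of mutated genes."""

    sample_id: str
    class_label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"sample {self.sample_id!r} has an empty gene set")


@dataclass
class Cohort:
    """An ordered collection of mutation profiles over a declared universe.

    ``truth`` optionally maps each class label to the ids of its planted
    driver terms (populated by the synthetic generator, absent for real
    data).
    """

    profiles: list[MutationProfile]
    universe: list[str]
    classes: list[str]
    truth: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        ids = [p.sample_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids in cohort")
        known = set(self.classes)
        for p in self.profiles:
            if p.class_label not in known:
                raise ValueError(
                    f"sample {p.sample_id!r} has unknown class {p.class_label!r}"
                )
        uni = set(self.universe)
        for p in self.profiles:
            if not p.genes <= uni:
                raise ValueError(
                    f"sample {p.sample_id!r} carries genes outside the universe"
                )

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.profiles]

    @property
    def labels(self) -> list[str]:
        return [p.class_label for p in self.profiles]


@dataclass
class AnnotationCatalog:
    """Named gene sets over an ordered universe.

    ``terms`` maps term id -> (namespace, gene set); namespace is ``"GO"``
    or ``"KEGG"``.  The universe size plays the role of the total gene
    count in the hypergeometric enrichment test.
    """

    universe: list[str]
    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for tid, (ns, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {tid!r} is empty")
            if not genes <= uni:
                raise ValueError(f"term {tid!r} has genes outside the universe")
            if ns not in ("GO", "KEGG"):
                raise ValueError(f"term {tid!r} has unknown namespace {ns!r}")

    @property
    def term_ids(self) -> list[str]:
        return list(self.terms)

    def term_genes(self, term_id: str) -> frozenset[str]:
        try:
            return self.terms[term_id][1]
        except KeyError:
            raise KeyError(f"unknown term id {term_id!r}") from None


@dataclass
class FeatureMatrix:
    """Samples x named features with a per-feature type tag.

    Stored as a dense float matrix; ``feature_types`` is aligned with
    ``feature_names``.  No missing values are permitted.
    """

    sample_ids: list[str]
    feature_names: list[str]
    feature_types: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, d = self.values.shape
        if len(self.sample_ids) != n or len(self.feature_names) != d:
            raise ValueError("dimension mismatch between names and values")
        if len(self.feature_types) != d:
            raise ValueError("feature_types length must equal feature count")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature names must be unique")
        bad = set(self.feature_types) - set(FEATURE_TYPES)
        if bad:
            raise ValueError(f"unknown feature types: {sorted(bad)}")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )

    def subset(self, features: Sequence[str]) -> "FeatureMatrix":
        """Column subset preserving the requested order."""
        pos = {f: i for i, f in enumerate(self.feature_names)}
        idx = [pos[f] for f in features]
        return FeatureMatrix(
            sample_ids=list(self.sample_ids),
            feature_names=list(features),
            feature_types=[self.feature_types[i] for i in idx],
            values=self.values[:, idx],
        )

    @staticmethod
    def concat(parts: Iterable["FeatureMatrix"]) -> "FeatureMatrix":
        """Horizontally stack matrices sharing the same sample order."""
        parts = list(parts)
        ids = parts[0].sample_ids
        for p in parts[1:]:
            if p.sample_ids != ids:
                raise ValueError("sample orders differ between matrices")
        return FeatureMatrix(
            sample_ids=list(ids),
            feature_names=[f for p in parts for f in p.feature_names],
            feature_types=[t for p in parts for t in p.feature_types],
            values=np.hstack([p.values for p in parts]),
        )

    def write_tsv(self, path: str | Path, types_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")
        if types_path is not None:
            Path(types_path).write_text(
                json.dumps(dict(zip(self.feature_names, self.feature_types)))
            )

    @staticmethod
    def read_tsv(path: str | Path, types_path: str | Path | None = None,
                 default_type: str = "enrichment") -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if types_path is not None:
            tmap: Mapping[str, str] = json.loads(Path(types_path).read_text())
            types = [tmap[c] for c in df.columns]
        else:
            types = [default_type] * df.shape[1]
        return FeatureMatrix(
            sample_ids=[str(s) for s in df.index],
            feature_names=[str(c) for c in df.columns],
            feature_types=types,
            values=df.to_numpy(dtype=float),
        )


@dataclass
class RankedList:
    """A method-tagged ordering of features with aligned importance scores."""

    method: str
    features: list[str]
    scores: list[float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.features) != len(self.scores):
            raise ValueError("features and scores must align")
        if len(set(self.features)) != len(self.features):
            raise ValueError("ranked list contains duplicate features")

    def top(self, k: int) -> list[str]:
        return self.features[:k]

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"rank": np.arange(1, len(self.features) + 1),
             "feature": self.features, "score": self.scores}
        )
        df.to_csv(path, sep="\t", index=False)
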