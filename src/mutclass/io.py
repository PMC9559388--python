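"""Readers and writers for the pipeline's plain-text interchange formats.

* MAF-lite TSV: one (sample_id, class, gene) row per sample-gene pair.
* GMT: tab-separated gene sets (term id, description, member genes).
* Edge list TSV: (gene_a, gene_b, weight) rows for the interaction graph.
* Truth JSON: class -> planted driver term ids (synthetic cohorts only).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .types import AnnotationCatalog, Cohort, MutationProfile

MAF_COLUMNS = ["sample_id", "class", "gene"]


def write_cohort_maf(cohort: Cohort, path: str | Path) -> None:
    rows = [
        (p.sample_id, p.class_label, g)
        for p in cohort.profiles
        for g in sorted(p.genes)
    ]
    pd.DataFrame(rows, columns=MAF_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cohort_maf(
    path: str | Path,
    universe: list[str] | None = None,
    truth: dict[str, list[str]] | None = None,
) -> Cohort:
    """Load a cohort from MAF-lite TSV.

    If ``universe`` is not given it is taken to be the sorted set of genes
    observed in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MAF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"MAF-lite file lacks columns {sorted(missing)}")
    profiles = []
    classes: list[str] = []
    for sid, grp in df.groupby("sample_id", sort=False):
        labels = grp["class"].unique()
        if len(labels) != 1:
            raise ValueError(f"sample {sid!r} has conflicting class labels")
        if labels[0] not in classes:
            classes.append(labels[0])
        profiles.append(
            MutationProfile(str(sid), str(labels[0]), frozenset(grp["gene"]))
        )
    if universe is None:
        universe = sorted({g for p in profiles for g in p.genes})
    return Cohort(profiles=profiles, universe=universe,
                  classes=sorted(classes), truth=truth)


def write_gmt(catalog: AnnotationCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, (ns, genes) in catalog.terms.items():
            fh.write("\t".join([tid, ns, *sorted(genes)]) + "\n")


def read_gmt(path: str | Path, universe: list[str] | None = None) -> AnnotationCatalog:
    """Load gene sets from GMT; the description field carries the namespace
    when it is ``GO``/``KEGG``, otherwise terms default to ``GO``."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            tid, desc, genes = parts[0], parts[1], parts[2:]
            ns = desc if desc in ("GO", "KEGG") else "GO"
            terms[tid] = (ns, frozenset(genes))
    if universe is None:
        universe = sorted({g for _, gs in terms.values() for g in gs})
    return AnnotationCatalog(universe=universe, terms=terms)


def write_edge_list(edges: list[tuple[str, str, float]], path: str | Path) -> None:
    pd.DataFrame(edges, columns=["gene_a", "gene_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    return [
        (str(a), str(b), float(w))
        for a, b, w in zip(df["gene_a"], df["gene_b"], df["weight"])
    ]


def write_truth(truth: dict[str, list[str]], path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2))


def read_truth(path: str | Path) -> dict[str, list[str]]:
    return json.loads(Path(path).read_text())


def read_labels(path: str | Path) -> pd.Series:
    """Labels file: TSV with columns sample_id, class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(df["class"].values, index=df["sample_id"].values)
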