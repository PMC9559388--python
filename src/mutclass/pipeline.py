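"""End-to-end orchestration of the synthetic study.

simulate -> encode (enrichment, text, network) -> merge -> screen ->
rank x4 -> incremental feature selection -> rule extraction ->
cross-method reports.  Every stage is seeded from the single pipeline
seed, so a run is reproducible from its config alone.

The pipeline defaults are desk-scale: 32-dimensional text and network
embeddings and shortened walks, which preserve the structure of the
analysis while keeping a full run in the minutes range on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .enrichment import encode_cohort_enrichment
from .ifs import IFSResult, run_ifs
from .network import WalkParams, embed_samples_network, generate_walks, train_node_embeddings
from .ranking import MCFSParams, rank_gbdt, rank_lasso, rank_mcfs, rank_mrmr
from .rules import (RuleSet, extract_rules, feature_type_breakdown,
                    intersect_feature_sets, IntersectionReport)
from .screening import ScreeningResult, boruta_screen
from .synthetic import SyntheticSpec, SyntheticStudy
from .text_features import build_corpus, embed_samples_text, train_gene_embeddings
from .types import FeatureMatrix, RankedList

RANKING_METHODS = ("lasso", "mrmr", "mcfs", "gbdt")


@dataclass(frozen=True)
class PipelineConfig:
    spec: SyntheticSpec = field(default_factory=SyntheticSpec)
    text_dim: int = 32
    text_window: int = 10
    text_epochs: int = 5
    network_dim: int = 32
    walk_length: int = 40
    walks_per_node: int = 5
    p: float = 1.0
    q: float = 1.0
    network_window: int = 5
    network_epochs: int = 3
    screen_max_iter: int = 50
    screen_alpha: float = 0.05
    screen_trees: int = 200
    ifs_step: int = 5
    ifs_classifier: str = "svm"
    ifs_method: str = "gbdt"
    folds: int = 10
    k_smote: int = 5
    feasible_delta: float = 0.05
    seed: int = 0


@dataclass
class PipelineResult:
    config: PipelineConfig
    features: FeatureMatrix
    screening: ScreeningResult
    screened: FeatureMatrix
    ranked: dict[str, RankedList]
    ifs: IFSResult
    rules: RuleSet
    intersection: IntersectionReport
    type_breakdown: dict[str, int]
    driver_rank_percentile: dict[str, float]
    labels: np.ndarray
    truth: dict[str, list[str]] | None


def driver_rank_percentile(ranked: RankedList, driver_features: set[str]) -> float:
    """Median 1-based rank of the driver features, as a percentage of the
    list length; features missing from the list count as worst rank."""
    total = len(ranked.features)
    pos = {f: i + 1 for i, f in enumerate(ranked.features)}
    ranks = [pos.get(f, total + 1) for f in sorted(driver_features)]
    return 100.0 * float(np.median(ranks)) / total


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    spec = config.spec
    seed = config.seed
    study = SyntheticStudy(spec)
    cohort, catalog, graph = study.cohort, study.catalog, study.graph
    y = np.asarray(cohort.labels)

    enr = encode_cohort_enrichment(cohort, catalog)

    corpus = build_corpus(cohort, seed=seed + 11)
    text_table = train_gene_embeddings(
        corpus, dim=config.text_dim, window=config.text_window,
        epochs=config.text_epochs, seed=seed + 12,
    )
    txt = embed_samples_text(cohort, text_table)

    walks = generate_walks(
        graph,
        WalkParams(p=config.p, q=config.q, walk_length=config.walk_length,
                   walks_per_node=config.walks_per_node, seed=seed + 13),
    )
    node_table = train_node_embeddings(
        walks, dim=config.network_dim, window=config.network_window,
        epochs=config.network_epochs, seed=seed + 14,
    )
    net = embed_samples_network(cohort, node_table)

    merged = FeatureMatrix.concat([enr, txt, net])

    screening = boruta_screen(
        merged, y, max_iter=config.screen_max_iter,
        alpha=config.screen_alpha, seed=seed + 21,
        n_estimators=config.screen_trees,
    )
    retained = [f for f in merged.feature_names if f in screening.accepted]
    if not retained:
        raise RuntimeError("screening retained no features")
    screened = merged.subset(retained)

    ranked = {
        "lasso": rank_lasso(screened, y, seed=seed + 31),
        "mrmr": rank_mrmr(screened, y),
        "mcfs": rank_mcfs(screened, y, MCFSParams(seed=seed + 33)),
        "gbdt": rank_gbdt(screened, y, seed=seed + 34),
    }

    ifs_result = run_ifs(
        screened, y, ranked[config.ifs_method],
        classifier=config.ifs_classifier, step=config.ifs_step,
        folds=config.folds, k_smote=config.k_smote, seed=seed + 41,
        feasible_delta=config.feasible_delta,
    )

    optimal_features = ranked[config.ifs_method].top(ifs_result.optimal_size)
    rules = extract_rules(screened, y, optimal_features, seed=seed + 51)

    k_feasible = ifs_result.feasible_size or ifs_result.optimal_size
    named_sets = {
        m: set(r.top(min(k_feasible, len(r.features))))
        for m, r in ranked.items()
    }
    intersection = intersect_feature_sets(named_sets)

    types = dict(zip(merged.feature_names, merged.feature_types))
    breakdown = feature_type_breakdown(retained, types)

    drivers: set[str] = set()
    if cohort.truth:
        for tids in cohort.truth.values():
            drivers |= set(tids)
    pct = {
        m: driver_rank_percentile(r, drivers) for m, r in ranked.items()
    } if drivers else {}

    return PipelineResult(
        config=config,
        features=merged,
        screening=screening,
        screened=screened,
        ranked=ranked,
        ifs=ifs_result,
        rules=rules,
        intersection=intersection,
        type_breakdown=breakdown,
        driver_rank_percentile=pct,
        labels=y,
        truth=cohort.truth,
    )


def write_pipeline_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Persist the pipeline's tables and reports as plain text."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.features.write_tsv(out / "features.tsv", out / "feature_types.json")
    for m, r in result.ranked.items():
        r.write_tsv(out / f"ranked_{m}.tsv")
    result.ifs.write_tsv(out / "ifs_curve.tsv")
    result.rules.write_text(out / "rules.txt")
    result.rules.write_json(out / "rules.json")
    (out / "intersection.json").write_text(result.intersection.to_json())
    import json

    (out / "summary.json").write_text(json.dumps(
        {
            "config": {**asdict(result.config),
                       "spec": asdict(result.config.spec)},
            "n_screened": result.screened.shape[1],
            "type_breakdown": result.type_breakdown,
            "ifs_optimal_size": result.ifs.optimal_size,
            "ifs_feasible_size": result.ifs.feasible_size,
            "ifs_optimal_weighted_f1": result.ifs.optimal_metrics.weighted_f1,
            "ifs_optimal_mcc": result.ifs.optimal_metrics.mcc,
            "driver_rank_percentile": result.driver_rank_percentile,
        },
        indent=2, default=str,
    ))
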