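"""End-to-end prioritization: weigh loci, train, score, evaluate."""

from __future__ import annotations

import logging
from dataclasses import asdict
from typing import Mapping, Sequence

import pandas as pd

from .boosting import (
    CVResult,
    FeatureMatrix,
    TrainingConfig,
    cross_validate,
    mendelian_loci,
)
from .evaluate import auroc, precision_at_recall, topk_permutation_test
from .loci import GeneAnnotation, LocusInterval
from .weighting import (
    GeneSetCollection,
    WeightingParams,
    enriched_gene_union,
    flag_likely_positives,
    term_enrichment,
    weigh_loci,
)

import numpy as np

log = logging.getLogger("locusboost")

__all__ = ["evidence_sets_for_trait", "prioritize", "evaluate_scores"]


def evidence_sets_for_trait(
    loci: Sequence[LocusInterval],
    collections: Mapping[str, GeneSetCollection],
    universe: Sequence[str],
    params: WeightingParams = WeightingParams(),
) -> dict[str, frozenset[str]]:
    """Per-source evidence gene sets from enrichment of the trait's loci.

    For each collection, terms over-represented among the trait's locus
    genes are selected and the union of their member genes becomes that
    source's evidence set (scored +5 for locus genes that belong to it).
    """
    locus_genes = {g for L in loci for g in L.member_genes}
    out = {}
    for src, coll in collections.items():
        terms = term_enrichment(
            locus_genes, coll, universe, params.adj_p_max, params.lod_min
        )
        out[src] = enriched_gene_union(terms, coll)
        log.info("evidence source %s: %d enriched terms, %d genes",
                 src, len(terms), len(out[src]))
    return out


def prioritize(
    loci: Sequence[LocusInterval],
    genome: Sequence[GeneAnnotation],
    collections: Mapping[str, GeneSetCollection],
    features: FeatureMatrix,
    config: TrainingConfig = TrainingConfig(),
    wparams: WeightingParams = WeightingParams(),
    positive_genes: Sequence[str] | None = None,
):
    """Run the full pipeline; returns (CVResult, weighted loci, report).

    GWA mode takes mapped loci; Mendelian mode takes ``positive_genes``
    (an unambiguous disease-gene list) instead and skips burn-in.
    """
    genes_by_id = {g.gene_id: g for g in genome}
    universe = [g.gene_id for g in genome]
    log.info("prioritize: mode=%s seed=%d params=%s", config.mode,
             config.seed, asdict(config))
    if config.mode == "mendelian":
        if not positive_genes:
            raise ValueError("mendelian mode requires positive_genes")
        weighted = mendelian_loci(positive_genes)
    else:
        evidence = evidence_sets_for_trait(loci, collections, universe, wparams)
        weighted = weigh_loci(
            loci, genes_by_id,
            evidence.get("omim", frozenset()),
            evidence.get("go", frozenset()),
            evidence.get("mpd", frozenset()),
            wparams,
        )
        log.info("burn-in: %d trees per fold before the main expansion",
                 config.n_burnin_trees)
    cv = cross_validate(weighted, features, universe, config)
    report = evaluate_scores(cv, weighted, wparams, seed=config.seed)
    return cv, weighted, report


def evaluate_scores(
    cv: CVResult,
    weighted,
    wparams: WeightingParams = WeightingParams(),
    seed: int = 0,
) -> dict:
    """AUROC / precision-at-recall / permutation report vs likely positives."""
    scores = cv.mean_scores()
    score_map = {g: float(v) for g, v in scores.items()}
    lp = flag_likely_positives(weighted, wparams.likely_positive_min)
    report: dict = {
        "seed": seed,
        "mode": cv.config.mode,
        "shrinkage": cv.config.shrinkage,
        "n_likely_positives": len(lp),
    }
    if lp and len(lp) < len(score_map):
        rep = precision_at_recall(score_map, lp, recall_level=0.2)
        report.update(
            auroc=rep.auroc,
            precision_at_recall=rep.precision_at_recall,
            recall_level=rep.recall_level,
            binom_p=rep.binom_p,
            n_predictions_at_threshold=rep.n_predictions_at_threshold,
        )
        ranked = [
            sorted(wl.gene_ids, key=lambda g: (-score_map[g], g))
            for wl in weighted
        ]
        try:
            perm = topk_permutation_test(
                ranked, lp, rng=np.random.default_rng(seed)
            )
            report["topk_observed"] = perm.observed_statistic
            report["topk_p"] = perm.empirical_p
        except ValueError:
            report["topk_p"] = None
    return report
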