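"""Prior-evidence weighting of candidate genes at GWAS loci.

Each gene at a multi-gene locus starts at 0 points and gains 5 points for
each line of prior evidence: a TSS within 50 kb of the index variant, and
membership in disease-relevant gene sets from three sources (an OMIM-like
Mendelian catalogue, enriched GO-like terms, enriched mouse-phenotype
terms), for a maximum of 20.  The sole gene of a single-gene locus gets a
fixed score of 1.  Scores are converted to per-locus sampling probabilities
(total probability 1 per locus) which drive the selection of positive
training examples during boosting.  Genes scoring >= 10 are flagged
"likely positives" and serve as surrogate truths for evaluation.

Evidence terms relevant to a trait are picked by over-representation of
the trait's locus genes within each term (one-sided hypergeometric test,
Benjamini-Hochberg adjusted, plus a log-odds cutoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .loci import GeneAnnotation, LocusInterval, TagSNP

__all__ = [
    "GeneSetCollection",
    "EvidenceScore",
    "WeightedLocus",
    "EnrichedTerm",
    "WeightingParams",
    "term_enrichment",
    "enriched_gene_union",
    "score_gene",
    "to_probabilities",
    "weigh_locus",
    "weigh_loci",
    "flag_likely_positives",
]


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (e.g. read from a GMT file)."""

    source: str
    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"{self.source}: empty gene set {term}")


@dataclass(frozen=True)
class EvidenceScore:
    proximity_pts: int = 0
    omim_pts: int = 0
    go_pts: int = 0
    mpd_pts: int = 0
    single_gene: bool = False

    @property
    def total(self) -> int:
        if self.single_gene:
            return 1
        return self.proximity_pts + self.omim_pts + self.go_pts + self.mpd_pts


@dataclass
class WeightedLocus:
    """A locus with per-gene prior scores, probabilities and LP flags."""

    locus: LocusInterval
    scores: dict[str, EvidenceScore]
    probabilities: dict[str, float]
    likely_positive: dict[str, bool]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.locus.member_genes)


@dataclass(frozen=True)
class EnrichedTerm:
    term_id: str
    p_value: float
    adj_p: float
    log_odds: float
    member_genes_at_loci: frozenset[str]


@dataclass(frozen=True)
class WeightingParams:
    evidence_pts: int = 5
    proximity_bp: int = 50_000
    likely_positive_min: int = 10
    adj_p_max: float = 0.05
    lod_min: float = 1.0


def _sample_log_odds(a: int, b: int, c: int, d: int, base: float = 10.0) -> float:
    """log_base of the sample odds ratio ad/bc, 0.5-corrected on zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return math.log((a * d) / (b * c), base)


def term_enrichment(
    locus_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    adj_p_max: float = 0.05,
    lod_min: float = 1.0,
    log_base: float = 10.0,
) -> list[EnrichedTerm]:
    """Terms over-represented among locus genes.

    One-sided hypergeometric upper-tail p per term, BH-adjusted across the
    collection; the log-odds score is the log (default base 10) of the
    sample odds ratio of the 2x2 table.  Terms pass with adj_p < adj_p_max
    and log_odds > lod_min; results are sorted by adjusted p (term id
    breaking ties).
    """
    universe = frozenset(universe)
    query = frozenset(locus_genes) & universe
    if not query:
        return []
    n_univ = len(universe)
    n_query = len(query)
    rows = []
    for term_id in sorted(collection.sets):
        term_genes = collection.sets[term_id] & universe
        if not term_genes:
            continue
        overlap = query & term_genes
        k, big_k = len(overlap), len(term_genes)
        p = float(hypergeom.sf(k - 1, n_univ, big_k, n_query))
        lod = _sample_log_odds(
            k, n_query - k, big_k - k, n_univ - n_query - big_k + k, log_base
        )
        rows.append((term_id, p, lod, frozenset(overlap)))
    if not rows:
        return []
    adj = multipletests([r[1] for r in rows], method="fdr_bh")[1]
    out = [
        EnrichedTerm(term_id, p, float(q), lod, overlap)
        for (term_id, p, lod, overlap), q in zip(rows, adj)
        if q < adj_p_max and lod > lod_min
    ]
    out.sort(key=lambda t: (t.adj_p, t.term_id))
    return out


def enriched_gene_union(terms: Sequence[EnrichedTerm], collection: GeneSetCollection) -> frozenset[str]:
    """All genes annotated to any enriched term (for +5 evidence points)."""
    genes: set[str] = set()
    for t in terms:
        genes |= collection.sets[t.term_id]
    return frozenset(genes)


def score_gene(
    gene: GeneAnnotation,
    locus: LocusInterval,
    tag: TagSNP,
    omim_genes: frozenset[str] | set[str],
    enriched_go_genes: frozenset[str] | set[str],
    enriched_mpd_genes: frozenset[str] | set[str],
    params: WeightingParams = WeightingParams(),
) -> EvidenceScore:
    """Prior score for one gene at one locus.

    +5 for a TSS within ``proximity_bp`` of the tag SNP, +5 per evidence
    source; a single-gene locus overrides everything with a total of 1.
    """
    if gene.gene_id not in locus.member_genes:
        raise ValueError(f"{gene.gene_id} is not a member of locus {tag.rsid}")
    if len(locus.member_genes) == 1:
        return EvidenceScore(single_gene=True)
    w = params.evidence_pts
    return EvidenceScore(
        proximity_pts=w if abs(gene.tss - tag.pos) <= params.proximity_bp else 0,
        omim_pts=w if gene.gene_id in omim_genes else 0,
        go_pts=w if gene.gene_id in enriched_go_genes else 0,
        mpd_pts=w if gene.gene_id in enriched_mpd_genes else 0,
    )


def to_probabilities(scores: Mapping[str, int | float]) -> dict[str, float]:
    """Normalize per-locus scores to probabilities summing to 1.

    All-zero loci fall back to a uniform distribution so that every locus
    can still contribute a positive training example.
    """
    if not scores:
        raise ValueError("no genes at locus")
    total = float(sum(scores.values()))
    if total <= 0:
        u = 1.0 / len(scores)
        return {g: u for g in scores}
    return {g: v / total for g, v in scores.items()}


def weigh_locus(
    locus: LocusInterval,
    genes_by_id: Mapping[str, GeneAnnotation],
    omim_genes: frozenset[str] | set[str],
    enriched_go_genes: frozenset[str] | set[str],
    enriched_mpd_genes: frozenset[str] | set[str],
    params: WeightingParams = WeightingParams(),
) -> WeightedLocus:
    scores = {
        gid: score_gene(
            genes_by_id[gid], locus, locus.tag,
            omim_genes, enriched_go_genes, enriched_mpd_genes, params,
        )
        for gid in locus.member_genes
    }
    probs = to_probabilities({g: s.total for g, s in scores.items()})
    lp = {g: s.total >= params.likely_positive_min for g, s in scores.items()}
    return WeightedLocus(locus=locus, scores=scores, probabilities=probs, likely_positive=lp)


def weigh_loci(
    loci: Sequence[LocusInterval],
    genes_by_id: Mapping[str, GeneAnnotation],
    omim_genes: frozenset[str] | set[str],
    enriched_go_genes: frozenset[str] | set[str],
    enriched_mpd_genes: frozenset[str] | set[str],
    params: WeightingParams = WeightingParams(),
) -> list[WeightedLocus]:
    """Weigh every non-empty locus; empty loci are dropped from training."""
    return [
        weigh_locus(L, genes_by_id, omim_genes, enriched_go_genes,
                    enriched_mpd_genes, params)
        for L in loci
        if not L.is_empty
    ]


def flag_likely_positives(
    weighted: Sequence[WeightedLocus], threshold: int = 10
) -> frozenset[str]:
    """Genes whose prior score reaches ``threshold`` at any locus."""
    out: set[str] = set()
    for wl in weighted:
        for g, s in wl.scores.items():
            if s.total >= threshold:
                out.add(g)
    return frozenset(out)
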