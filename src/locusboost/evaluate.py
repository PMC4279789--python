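"""Performance and significance statistics for gene prioritization.

Four complementary views of a score table:

* AUROC — probability that a random positive outranks a random negative
  (rank-based Mann-Whitney form with midrank tie handling);
* precision at fixed recall, with a binomial tail p-value for the count
  of positives inside the smallest top-k capturing that recall;
* a within-locus rank permutation test — how often a "likely positive"
  lands in the top-k of its locus (k = 3, or 2 for three-gene loci, or 1
  for two-gene loci), against a null of uniformly permuted ranks;
* an empirical top-score-at-locus null — the best score among n genes
  drawn from the genome-wide score distribution — plus Fisher-style
  enrichment of one gene set in another over a fixed universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom, hypergeom, rankdata

__all__ = [
    "EvalReport",
    "PermutationResult",
    "auroc",
    "precision_at_recall",
    "topk_permutation_test",
    "top_score_null",
    "fisher_enrichment",
]


@dataclass
class EvalReport:
    auroc: float
    precision_at_recall: float
    recall_level: float
    binom_p: float
    n_predictions_at_threshold: int


@dataclass
class PermutationResult:
    observed_statistic: int
    null_counts: np.ndarray  # histogram over statistic values 0..n_loci
    empirical_p: float
    n_perm: int


def _ordered(scores: Mapping[str, float]) -> list[str]:
    """Gene ids best-first; ties broken by gene id for determinism."""
    return sorted(scores, key=lambda g: (-scores[g], g))


def auroc(scores: Mapping[str, float], positives: set[str] | frozenset[str]) -> float:
    """Rank-based AUROC (Mann-Whitney U / n1*n0) with midrank ties."""
    genes = list(scores)
    labels = np.array([g in positives for g in genes])
    n1 = int(labels.sum())
    n0 = len(genes) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = rankdata([scores[g] for g in genes])
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def precision_at_recall(
    scores: Mapping[str, float],
    positives: set[str] | frozenset[str],
    recall_level: float = 0.2,
) -> EvalReport:
    """Precision in the smallest top-k capturing ``recall_level`` of positives.

    The binomial p is P(X >= observed positives in the top-k) for
    X ~ Binomial(k, prevalence), prevalence being the overall positive
    fraction — the chance a random same-sized subset does as well.
    """
    if not (0.0 < recall_level <= 1.0):
        raise ValueError("recall_level must be in (0, 1]")
    order = _ordered(scores)
    n = len(order)
    n_pos = sum(1 for g in order if g in positives)
    if n_pos == 0:
        raise ValueError("no positives among scored genes")
    cum = 0
    k = n
    hits = n_pos
    for i, g in enumerate(order, start=1):
        if g in positives:
            cum += 1
        if cum / n_pos >= recall_level:
            k, hits = i, cum
            break
    precision = hits / k
    prevalence = n_pos / n
    p = float(binom.sf(hits - 1, k, prevalence))
    return EvalReport(
        auroc=auroc(scores, positives),
        precision_at_recall=precision,
        recall_level=recall_level,
        binom_p=p,
        n_predictions_at_threshold=k,
    )


def _window(n_genes: int) -> int:
    """Top-k window per locus size: 3 for >=4 genes, 2 for 3, 1 for 2."""
    if n_genes >= 4:
        return 3
    if n_genes == 3:
        return 2
    return 1


def topk_permutation_test(
    ranked_loci: Sequence[Sequence[str]],
    likely_positives: set[str] | frozenset[str],
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Within-locus rank permutation test for likely-positive prioritization.

    ``ranked_loci`` lists each locus's genes best-first under the observed
    scores.  Only loci holding at least one likely positive and at least
    two genes contribute (a single-gene locus is trivially top-ranked).
    The statistic counts contributing loci with a likely positive inside
    the size-dependent top-k window; the null permutes ranks uniformly and
    independently within each locus.  Empirical p uses the +1 correction:
    (#null >= observed + 1) / (n_perm + 1).
    """
    rng = np.random.default_rng() if rng is None else rng
    contributing = []
    for genes in ranked_loci:
        n_lp = sum(1 for g in genes if g in likely_positives)
        if n_lp >= 1 and len(genes) >= 2:
            contributing.append((list(genes), n_lp))
    if not contributing:
        raise ValueError("no contributing loci (need >=1 likely positive, >=2 genes)")
    observed = 0
    null = np.zeros(n_perm, dtype=np.int64)
    for genes, n_lp in contributing:
        m = len(genes)
        k = _window(m)
        if any(g in likely_positives for g in genes[:k]):
            observed += 1
        # under a uniform rank permutation the number of LPs in the top-k
        # is hypergeometric(m; n_lp; k)
        null += rng.hypergeometric(n_lp, m - n_lp, k, size=n_perm) > 0
    p = (int((null >= observed).sum()) + 1) / (n_perm + 1)
    counts = np.bincount(null, minlength=len(contributing) + 1)
    return PermutationResult(
        observed_statistic=observed,
        null_counts=counts,
        empirical_p=float(p),
        n_perm=n_perm,
    )


def top_score_null(
    locus_gene_counts: Sequence[int],
    global_scores: Sequence[float],
    observed_top: Sequence[float],
    n_iter: int = 10_000,
    rng: np.random.Generator | None = None,
    with_replacement: bool = False,
) -> list[float]:
    """Per-locus empirical p for the observed top score.

    For a locus of n genes, n scores are drawn from the genome-wide score
    distribution (without replacement within an iteration by default —
    a locus's genes are distinct) and the maximum recorded; p is the
    fraction of iterations whose maximum reaches the observed top score.
    """
    rng = np.random.default_rng() if rng is None else rng
    pool = np.asarray(global_scores, dtype=float)
    if pool.size == 0:
        raise ValueError("empty global score pool")
    if len(locus_gene_counts) != len(observed_top):
        raise ValueError("one observed top score per locus required")
    out = []
    for n, obs in zip(locus_gene_counts, observed_top):
        if n < 1:
            raise ValueError("locus must contain at least one gene")
        if not with_replacement and n > pool.size:
            raise ValueError(f"cannot draw {n} distinct scores from {pool.size}")
        if with_replacement:
            tops = pool[rng.integers(0, pool.size, size=(n_iter, n))].max(axis=1)
        else:
            tops = np.array(
                [pool[rng.choice(pool.size, size=n, replace=False)].max()
                 for _ in range(n_iter)]
            )
        out.append(float((tops >= obs).mean()))
    return out


def fisher_enrichment(
    n_overlap: int, n_set_a: int, n_set_b: int, n_universe: int
) -> tuple[float, float]:
    """Enrichment of one gene set in another over a fixed universe.

    Returns the sample odds ratio ad/bc of the 2x2 table (0.5 continuity
    correction when any cell is zero) and the one-sided hypergeometric
    over-representation p.
    """
    a = n_overlap
    b = n_set_b - a
    c = n_set_a - a
    d = n_universe - a - b - c
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent 2x2 counts")
    p = float(hypergeom.sf(a - 1, n_universe, n_set_a, n_set_b))
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c), p
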