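"""Adapted stochastic gradient boosting for locus-aware gene classification.

Standard gradient boosting assumes the positive training labels are known.
At a GWAS locus they are not: any member gene could be causal.  The
adaptation here samples, for each tree, one positive example per locus
according to the locus's per-gene prior probabilities, together with an
equal number of negatives drawn from genes outside all loci.  Trees are
small LAD (absolute-loss) regression trees: four terminal leaves, grown
best-first on binary features, leaf values being medians of residuals.
The ensemble prediction F(x) starts at the median of the first batch's
0/1 targets and accumulates shrinkage-scaled tree outputs; the reported
score is the logit of F(x) clamped to [eps, 1-eps].

Two training refinements follow the locus-aware design:

* burn-in (GWA mode): 20 preliminary trees are grown; after each, the
  top-scoring gene at every training locus earns +1 on a running tally.
  Afterwards only genes holding >25% of their locus's tally keep nonzero
  sampling probability; the burn-in trees themselves are discarded.
* cross-validation: six rounds of eight-fold CV over loci (GWA) or over
  positive genes (Mendelian; no burn-in).  Each gene at a held-out locus
  is scored by the fold model that never trained on its locus, and genes
  outside all loci receive the mean over a round's fold models, so every
  gene in the annotation universe gets a score untouched by its own label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .loci import LocusInterval, TagSNP
from .weighting import EvidenceScore, WeightedLocus

__all__ = [
    "FeatureMatrix",
    "RegressionTree",
    "BoostedModel",
    "TrainingConfig",
    "SampledBatch",
    "CVResult",
    "fit_lad_tree",
    "sample_batch",
    "Booster",
    "boost",
    "predict_log_odds",
    "apply_burnin_filter",
    "burnin_refine",
    "mendelian_loci",
    "default_negatives_pool",
    "cross_validate",
]


class FeatureMatrix:
    """Binary gene x feature matrix with zero-imputation for absent genes."""

    missing_policy = "zero"

    def __init__(
        self,
        gene_ids: Sequence[str],
        feature_ids: Sequence[str],
        values,
    ) -> None:
        X = np.asarray(values)
        if hasattr(values, "toarray"):  # scipy sparse
            X = values.toarray()
        X = np.asarray(X, dtype=np.uint8)
        if X.shape != (len(gene_ids), len(feature_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("feature matrix entries must be 0/1")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(feature_ids)) != len(feature_ids):
            raise ValueError("duplicate feature ids")
        self.gene_ids = list(gene_ids)
        self.feature_ids = list(feature_ids)
        self.X = X
        self._row = {g: i for i, g in enumerate(self.gene_ids)}

    @classmethod
    def from_triplets(
        cls,
        triplets: Iterable[tuple[str, str, int]],
        gene_ids: Sequence[str] | None = None,
        feature_ids: Sequence[str] | None = None,
    ) -> "FeatureMatrix":
        trips = list(triplets)
        if gene_ids is None:
            gene_ids = sorted({g for g, _, _ in trips})
        if feature_ids is None:
            feature_ids = sorted({f for _, f, _ in trips})
        gi = {g: i for i, g in enumerate(gene_ids)}
        fi = {f: i for i, f in enumerate(feature_ids)}
        X = np.zeros((len(gene_ids), len(feature_ids)), dtype=np.uint8)
        for g, f, v in trips:
            X[gi[g], fi[f]] = 1 if v else 0
        return cls(gene_ids, feature_ids, X)

    def rows(self, ids: Sequence[str]) -> np.ndarray:
        """Feature rows for ``ids``; genes absent from the matrix impute to 0."""
        out = np.zeros((len(ids), len(self.feature_ids)), dtype=np.uint8)
        for i, g in enumerate(ids):
            j = self._row.get(g)
            if j is not None:
                out[i] = self.X[j]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.gene_ids, columns=self.feature_ids)


# ---------------------------------------------------------------------------
# LAD regression trees


@dataclass
class _Node:
    feature: int | None = None
    value: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None

    def to_dict(self) -> dict:
        if self.feature is None:
            return {"value": self.value}
        return {
            "split_feature": self.feature,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Node":
        if "value" in d:
            return cls(value=float(d["value"]))
        return cls(
            feature=int(d["split_feature"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass
class RegressionTree:
    """A small binary-feature regression tree (left = 0, right = 1)."""

    root: _Node

    @property
    def n_leaves(self) -> int:
        def count(n: _Node) -> int:
            return 1 if n.feature is None else count(n.left) + count(n.right)

        return count(self.root)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        out = np.empty(X.shape[0])

        def fill(node: _Node, mask: np.ndarray) -> None:
            if node.feature is None:
                out[mask] = node.value
                return
            right = X[:, node.feature] != 0
            fill(node.left, mask & ~right)
            fill(node.right, mask & right)

        fill(self.root, np.ones(X.shape[0], dtype=bool))
        return out

    def to_dict(self) -> dict:
        return self.root.to_dict()

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        return cls(root=_Node.from_dict(d))


def _sorted_l1(rsort: np.ndarray) -> float:
    """L1 deviation from the median of an ascending-sorted vector."""
    c = rsort.size
    if c == 0:
        return 0.0
    a = c // 2
    return float(rsort[c - a :].sum() - rsort[:a].sum())


def _split_losses(sub: np.ndarray, rs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature post-split L1 losses for one leaf.

    Returns (loss_left, loss_right, valid) over all features, where valid
    marks features that actually split the leaf.  Uses per-column running
    sums over the residuals sorted once, so the median-absolute-deviation
    of each side comes out of cumulative order statistics without a Python
    loop over features.
    """
    n, p = sub.shape
    order = np.argsort(rs, kind="stable")
    rsort = rs[order]
    M = sub[order].astype(bool)
    c1 = M.sum(axis=0)
    valid = (c1 > 0) & (c1 < n)

    S1 = np.cumsum(np.where(M, rsort[:, None], 0.0), axis=0)
    C1 = np.cumsum(M, axis=0)
    S0 = np.cumsum(rsort)[:, None] - S1
    C0 = np.arange(1, n + 1)[:, None] - C1
    cols = np.arange(p)

    def sum_smallest(S: np.ndarray, C: np.ndarray, k: np.ndarray) -> np.ndarray:
        kk = np.maximum(k, 1)
        first = (C >= kk[None, :]).argmax(axis=0)
        return np.where(k > 0, S[first, cols], 0.0)

    def side_l1(S: np.ndarray, C: np.ndarray, c: np.ndarray) -> np.ndarray:
        # L1 around the median = (sum of largest c-a) - (sum of smallest a)
        total = S[-1] if S.ndim == 1 else S[-1, :]
        a = c // 2
        return (total - sum_smallest(S, C, c - a)) - sum_smallest(S, C, a)

    return side_l1(S0, C0, n - c1), side_l1(S1, C1, c1), valid


def fit_lad_tree(X: np.ndarray, residuals: np.ndarray, n_leaves: int = 4) -> RegressionTree:
    """Grow a LAD regression tree on binary features, best-first.

    At each step the (leaf, feature) pair giving the largest reduction in
    total absolute deviation from per-side medians is split, until
    ``n_leaves`` leaves exist or no split reduces the loss.  Leaf values
    are medians of the residuals they contain.  Ties break on the lowest
    feature index, then the earliest-created leaf.
    """
    X = np.atleast_2d(np.asarray(X))
    r = np.asarray(residuals, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")

    root = _Node()
    # leaf bookkeeping: (node, example indices, best_gain, best_feature)
    def evaluate(idx: np.ndarray) -> tuple[float, int]:
        rs = r[idx]
        if idx.size < 2:
            return 0.0, -1
        parent = _sorted_l1(np.sort(rs, kind="stable"))
        l0, l1, valid = _split_losses(X[idx], rs)
        gains = np.where(valid, parent - l0 - l1, -np.inf)
        f = int(np.argmax(gains))
        return (float(gains[f]), f) if np.isfinite(gains[f]) else (0.0, -1)

    all_idx = np.arange(X.shape[0])
    leaves: list[tuple[_Node, np.ndarray, float, int]] = [
        (root, all_idx, *evaluate(all_idx))
    ]
    eps = 1e-12
    while len(leaves) < n_leaves:
        best_i = -1
        best_gain = eps
        for i, (_, _, gain, f) in enumerate(leaves):
            if f >= 0 and gain > best_gain:
                best_gain, best_i = gain, i
        if best_i < 0:
            break
        node, idx, _, f = leaves.pop(best_i)
        right = X[idx, f] != 0
        node.feature = f
        node.left = _Node()
        node.right = _Node()
        li, ri = idx[~right], idx[right]
        leaves.append((node.left, li, *evaluate(li)))
        leaves.append((node.right, ri, *evaluate(ri)))

    for node, idx, _, _ in leaves:
        node.value = float(np.median(r[idx]))
    return RegressionTree(root=root)


# ---------------------------------------------------------------------------
# Boosting


@dataclass
class BoostedModel:
    """Additive expansion F(x) = f0 + shrinkage * sum of tree outputs."""

    f0: float
    shrinkage: float
    trees: list[RegressionTree] = field(default_factory=list)
    train_log: list[tuple[float, float]] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        F = np.full(X.shape[0], self.f0)
        for t in self.trees:
            F += self.shrinkage * t.predict(X)
        return F

    def to_dict(self) -> dict:
        return {
            "format": "locusboost-model",
            "version": 1,
            "f0": self.f0,
            "shrinkage": self.shrinkage,
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoostedModel":
        if d.get("format") != "locusboost-model":
            raise ValueError("not a locusboost model record")
        return cls(
            f0=float(d["f0"]),
            shrinkage=float(d["shrinkage"]),
            trees=[RegressionTree.from_dict(t) for t in d["trees"]],
        )


def predict_log_odds(
    model: BoostedModel, X: np.ndarray, epsilon: float = 1e-3
) -> np.ndarray:
    """Log-odds of disease association: logit of F(x) clamped to [eps, 1-eps]."""
    p = np.clip(model.predict(X), epsilon, 1.0 - epsilon)
    return np.log(p / (1.0 - p))


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyper-parameters (defaults are the operating settings)."""

    mode: str = "gwa"
    n_rounds: int = 6
    n_folds: int = 8
    n_main_trees: int = 60
    n_burnin_trees: int = 20
    n_leaves: int = 4
    locus_fraction: float = 0.7
    shrinkage: float = 0.1
    burnin_keep_fraction: float = 0.25
    epsilon: float = 1e-3
    tally_includes_initial: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("gwa", "mendelian"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 < self.locus_fraction <= 1.0):
            raise ValueError("locus_fraction must be in (0, 1]")
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")


@dataclass
class SampledBatch:
    positives: list[str]
    negatives: list[str]
    locus_indices: list[int]


def sample_batch(
    weighted_loci: Sequence[WeightedLocus],
    negatives_pool: Sequence[str],
    locus_fraction: float,
    rng: np.random.Generator,
) -> SampledBatch:
    """One positive per sampled locus (by prior probability), matched negatives.

    ceil(locus_fraction * L) loci are chosen uniformly without replacement;
    negatives are drawn uniformly without replacement from the pool, which
    must be disjoint from all locus member genes.
    """
    L = len(weighted_loci)
    if L == 0:
        raise ValueError("no loci to sample from")
    n_sel = math.ceil(locus_fraction * L)
    if len(negatives_pool) < n_sel:
        raise ValueError(
            f"negatives pool ({len(negatives_pool)}) smaller than batch ({n_sel})"
        )
    chosen = np.sort(rng.choice(L, size=n_sel, replace=False))
    positives = []
    for li in chosen:
        wl = weighted_loci[li]
        genes = wl.gene_ids
        p = np.array([wl.probabilities[g] for g in genes], dtype=float)
        p = p / p.sum()
        positives.append(genes[int(rng.choice(len(genes), p=p))])
    neg_idx = rng.choice(len(negatives_pool), size=n_sel, replace=False)
    negatives = [negatives_pool[i] for i in neg_idx]
    return SampledBatch(positives, negatives, [int(i) for i in chosen])


class Booster:
    """Incremental trainer that keeps the running prediction for all genes.

    Maintains F(x) over every locus gene and pool gene so burn-in can read
    current top genes per locus without re-evaluating the whole ensemble.
    """

    def __init__(
        self,
        weighted_loci: Sequence[WeightedLocus],
        features: FeatureMatrix,
        negatives_pool: Sequence[str],
        config: TrainingConfig,
        rng: np.random.Generator,
    ) -> None:
        if not weighted_loci:
            raise ValueError("at least one weighted locus required")
        self.loci = list(weighted_loci)
        self.config = config
        self.rng = rng
        self.pool = list(negatives_pool)
        ids: list[str] = []
        seen: set[str] = set()
        for wl in self.loci:
            for g in wl.gene_ids:
                if g not in seen:
                    seen.add(g)
                    ids.append(g)
        for g in self.pool:
            if g not in seen:
                seen.add(g)
                ids.append(g)
        self.ids = ids
        self.index = {g: i for i, g in enumerate(ids)}
        self.X = features.rows(ids)
        self.f0: float | None = None
        self.F: np.ndarray | None = None
        self.trees: list[RegressionTree] = []
        self.train_log: list[tuple[float, float]] = []

    def step(self) -> None:
        batch = sample_batch(
            self.loci, self.pool, self.config.locus_fraction, self.rng
        )
        genes = batch.positives + batch.negatives
        rows = np.array([self.index[g] for g in genes])
        y = np.concatenate(
            [np.ones(len(batch.positives)), np.zeros(len(batch.negatives))]
        )
        if self.f0 is None:
            self.f0 = float(np.median(y))
            self.F = np.full(len(self.ids), self.f0)
        r = y - self.F[rows]
        tree = fit_lad_tree(self.X[rows], r, self.config.n_leaves)
        fitted = tree.predict(self.X[rows])
        self.train_log.append(
            (float(np.abs(r).sum()), float(np.abs(r - fitted).sum()))
        )
        self.trees.append(tree)
        self.F = self.F + self.config.shrinkage * tree.predict(self.X)

    def locus_top_gene(self, wl: WeightedLocus) -> str:
        """Member gene with the highest current F; ties to the lower gene id."""
        assert self.F is not None
        best = None
        best_val = -np.inf
        for g in sorted(wl.gene_ids):
            v = self.F[self.index[g]]
            if v > best_val:
                best, best_val = g, v
        return best

    def model(self) -> BoostedModel:
        m = BoostedModel(
            f0=self.f0 if self.f0 is not None else 0.5,
            shrinkage=self.config.shrinkage,
            trees=list(self.trees),
        )
        m.train_log = list(self.train_log)
        return m


def boost(
    weighted_loci: Sequence[WeightedLocus],
    features: FeatureMatrix,
    negatives_pool: Sequence[str],
    n_trees: int,
    config: TrainingConfig,
    rng: np.random.Generator,
) -> BoostedModel:
    """Train an ensemble of ``n_trees`` LAD trees from per-locus samples."""
    b = Booster(weighted_loci, features, negatives_pool, config, rng)
    for _ in range(n_trees):
        b.step()
    return b.model()


def apply_burnin_filter(
    totals: Mapping[str, float], keep_fraction: float = 0.25
) -> frozenset[str]:
    """Genes holding more than ``keep_fraction`` of the locus tally.

    Single-gene loci are always retained; if no gene clears the cutoff the
    top-scoring gene (ties to the lower id) is kept so the locus stays
    usable as a source of positives.
    """
    if not totals:
        raise ValueError("empty locus tally")
    if len(totals) == 1:
        return frozenset(totals)
    cutoff = keep_fraction * sum(totals.values())
    kept = frozenset(g for g, v in totals.items() if v > cutoff)
    if not kept:
        kept = frozenset({min(totals, key=lambda g: (-totals[g], g))})
    return kept


def burnin_refine(
    weighted_loci: Sequence[WeightedLocus],
    features: FeatureMatrix,
    negatives_pool: Sequence[str],
    config: TrainingConfig,
    rng: np.random.Generator,
) -> list[WeightedLocus]:
    """Burn-in phase: narrow each locus's positive candidates.

    Grows ``n_burnin_trees`` trees; after each, the gene with the highest
    current score at every training locus gains +1 on a running tally.
    Genes holding more than ``burnin_keep_fraction`` of their locus tally
    (initial prior + increments by default) keep their tally as the new
    sampling weight; all other genes drop to probability 0.  The burn-in
    trees themselves are discarded.
    """
    b = Booster(weighted_loci, features, negatives_pool, config, rng)
    increments: list[dict[str, int]] = [dict() for _ in weighted_loci]
    for _ in range(config.n_burnin_trees):
        b.step()
        for li, wl in enumerate(weighted_loci):
            top = b.locus_top_gene(wl)
            increments[li][top] = increments[li].get(top, 0) + 1
    refined = []
    for wl, inc in zip(weighted_loci, increments):
        totals = {
            g: (wl.scores[g].total if config.tally_includes_initial else 0)
            + inc.get(g, 0)
            for g in wl.gene_ids
        }
        kept = apply_burnin_filter(totals, config.burnin_keep_fraction)
        mass = sum(totals[g] for g in kept)
        probs = {
            g: (totals[g] / mass if g in kept else 0.0) for g in wl.gene_ids
        }
        refined.append(
            WeightedLocus(
                locus=wl.locus,
                scores=dict(wl.scores),
                probabilities=probs,
                likely_positive=dict(wl.likely_positive),
            )
        )
    return refined


def mendelian_loci(positive_genes: Sequence[str]) -> list[WeightedLocus]:
    """Wrap an unambiguous disease-gene list as degenerate single-gene loci."""
    out = []
    for g in positive_genes:
        tag = TagSNP(rsid=f"gene:{g}", chrom="NA", pos=0, trait="mendelian")
        locus = LocusInterval(tag=tag, chrom="NA", start=0, end=1, member_genes=[g])
        out.append(
            WeightedLocus(
                locus=locus,
                scores={g: EvidenceScore(single_gene=True)},
                probabilities={g: 1.0},
                likely_positive={g: True},
            )
        )
    return out


def default_negatives_pool(
    universe_ids: Sequence[str], weighted_loci: Sequence[WeightedLocus]
) -> list[str]:
    """All annotated genes that belong to no locus, in universe order."""
    locus_genes = {g for wl in weighted_loci for g in wl.gene_ids}
    return [g for g in universe_ids if g not in locus_genes]


@dataclass
class CVResult:
    """Cross-validated genome-wide score table plus run diagnostics."""

    scores: pd.DataFrame  # index gene_id, columns round_1..n + mean_log_odds
    fold_assignments: list[list[list[int]]]  # [round][fold] -> locus indices
    trees_per_fold: list[list[int]]
    config: TrainingConfig

    def mean_scores(self) -> pd.Series:
        return self.scores["mean_log_odds"]


def cross_validate(
    weighted_loci: Sequence[WeightedLocus],
    features: FeatureMatrix,
    universe_ids: Sequence[str],
    config: TrainingConfig,
    negatives_pool: Sequence[str] | None = None,
) -> CVResult:
    """Cross-validated genome-wide log-odds of disease association.

    Per round, loci are partitioned into ``n_folds`` folds; each fold's
    model trains on the remaining loci (burn-in then ``n_main_trees``
    trees in GWA mode, ``n_main_trees`` trees only in Mendelian mode) and
    scores every universe gene.  A locus gene's round score comes from the
    fold holding out its locus (mean if it sits at several loci); all
    other genes take the mean over the round's fold models.  The final
    score is the mean over rounds.  Bit-reproducible given config.seed.
    """
    loci = list(weighted_loci)
    L = len(loci)
    if L < config.n_folds:
        raise ValueError(f"need >= {config.n_folds} loci, got {L}")
    if negatives_pool is None:
        negatives_pool = default_negatives_pool(universe_ids, loci)
    universe_ids = list(universe_ids)
    Xu = features.rows(universe_ids)
    uindex = {g: i for i, g in enumerate(universe_ids)}

    ss = np.random.SeedSequence(config.seed)
    round_seqs = ss.spawn(config.n_rounds)
    round_cols = {}
    fold_assignments: list[list[list[int]]] = []
    trees_per_fold: list[list[int]] = []

    for r, rseq in enumerate(round_seqs):
        perm_rng = np.random.default_rng(rseq)
        perm = perm_rng.permutation(L)
        folds = [list(map(int, f)) for f in np.array_split(perm, config.n_folds)]
        fold_assignments.append(folds)
        fold_seqs = rseq.spawn(config.n_folds)
        fold_preds = np.zeros((config.n_folds, len(universe_ids)))
        held: dict[int, list[float]] = {}
        n_trees_log = []
        for k, (fold, fseq) in enumerate(zip(folds, fold_seqs)):
            train = [loci[i] for i in range(L) if i not in fold]
            if not train:
                raise ValueError(f"round {r} fold {k} has no training loci")
            frng = np.random.default_rng(fseq)
            if config.mode == "gwa":
                refined = burnin_refine(
                    train, features, negatives_pool, config, frng
                )
                model = boost(
                    refined, features, negatives_pool,
                    config.n_main_trees, config, frng,
                )
            else:
                model = boost(
                    train, features, negatives_pool,
                    config.n_main_trees, config, frng,
                )
            n_trees_log.append(len(model.trees))
            preds = predict_log_odds(model, Xu, config.epsilon)
            fold_preds[k] = preds
            for li in fold:
                for g in loci[li].gene_ids:
                    held.setdefault(uindex[g], []).append(float(preds[uindex[g]]))
        trees_per_fold.append(n_trees_log)
        col = fold_preds.mean(axis=0)
        for gi, vals in held.items():
            col[gi] = float(np.mean(vals))
        round_cols[f"round_{r + 1}"] = col

    df = pd.DataFrame(round_cols, index=universe_ids)
    df["mean_log_odds"] = df.mean(axis=1)
    if not np.isfinite(df.to_numpy()).all():
        raise AssertionError("non-finite score produced")
    return CVResult(
        scores=df,
        fold_assignments=fold_assignments,
        trees_per_fold=trees_per_fold,
        config=config,
    )
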