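"""LAD trees, per-locus sampling, burn-in refinement, cross-validation."""

import math

import numpy as np
import pytest

from locusboost.boosting import (
    BoostedModel,
    FeatureMatrix,
    TrainingConfig,
    apply_burnin_filter,
    boost,
    burnin_refine,
    cross_validate,
    default_negatives_pool,
    fit_lad_tree,
    mendelian_loci,
    predict_log_odds,
    sample_batch,
)
from locusboost.pipeline import evidence_sets_for_trait
from locusboost.weighting import weigh_loci


# ---------------------------------------------------------------------------
# independent oracle: greedy best-first growth with naive exhaustive search


def naive_greedy_loss(X, r, n_leaves):
    r = np.asarray(r, dtype=float)

    def l1(idx):
        if not idx:
            return 0.0
        v = r[list(idx)]
        return float(np.abs(v - np.median(v)).sum())

    leaves = [list(range(len(r)))]
    while len(leaves) < n_leaves:
        best = None
        for li, idx in enumerate(leaves):
            for f in range(X.shape[1]):
                left = [i for i in idx if X[i, f] == 0]
                right = [i for i in idx if X[i, f] == 1]
                if not left or not right:
                    continue
                gain = l1(idx) - l1(left) - l1(right)
                if gain > 1e-12 and (best is None or gain > best[0] + 1e-12):
                    best = (gain, li, left, right)
        if best is None:
            break
        _, li, left, right = best
        leaves.pop(li)
        leaves.extend([left, right])
    return sum(l1(idx) for idx in leaves)


class TestLadTree:
    def test_perfect_split(self):
        X = np.array([[1], [1], [0], [0]])
        r = np.array([1.0, 1.0, 0.0, 0.0])
        tree = fit_lad_tree(X, r, n_leaves=4)
        assert tree.n_leaves == 2
        assert tree.predict(X) == pytest.approx(r)

    def test_constant_targets_single_leaf(self):
        X = np.array([[0, 1], [1, 0], [1, 1]])
        tree = fit_lad_tree(X, np.full(3, 0.7), n_leaves=4)
        assert tree.n_leaves == 1
        assert tree.predict(X) == pytest.approx([0.7, 0.7, 0.7])

    def test_constant_features_single_leaf(self):
        X = np.ones((5, 3))
        r = np.array([0.1, 0.5, 0.9, 0.2, 0.8])
        tree = fit_lad_tree(X, r, n_leaves=4)
        assert tree.n_leaves == 1
        assert tree.predict(X)[0] == pytest.approx(np.median(r))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_greedy_oracle(self, seed):
        """Total absolute loss equals a naive best-first exhaustive search
        on random 12-example, 8-feature batches."""
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, size=(12, 8))
        r = rng.normal(size=12)
        tree = fit_lad_tree(X, r, n_leaves=4)
        loss = float(np.abs(r - tree.predict(X)).sum())
        assert loss == pytest.approx(naive_greedy_loss(X, r, 4), abs=1e-9)
        assert tree.n_leaves <= 4

    def test_leaf_cap_respected(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 2, size=(40, 10))
        tree = fit_lad_tree(X, rng.normal(size=40), n_leaves=3)
        assert tree.n_leaves <= 3


def toy_weighted(n_loci=10, genes_per=3, probs=None):
    """Minimal weighted loci over synthetic ids (no genome needed)."""
    from locusboost.loci import LocusInterval, TagSNP
    from locusboost.weighting import EvidenceScore, WeightedLocus

    out = []
    for li in range(n_loci):
        gids = [f"L{li}_g{j}" for j in range(genes_per)]
        p = probs or {g: 1.0 / genes_per for g in gids}
        if probs:
            p = {g: probs[j] for j, g in enumerate(gids)}
        tag = TagSNP(f"rs{li}", "chr1", 100 + li, "t")
        locus = LocusInterval(tag=tag, chrom="chr1", start=0, end=10**6,
                              member_genes=gids)
        out.append(
            WeightedLocus(
                locus=locus,
                scores={g: EvidenceScore() for g in gids},
                probabilities=p,
                likely_positive={g: False for g in gids},
            )
        )
    return out


class TestSampleBatch:
    def test_counts_70_percent(self):
        loci = toy_weighted(n_loci=10)
        pool = [f"n{i}" for i in range(50)]
        batch = sample_batch(loci, pool, 0.7, np.random.default_rng(0))
        assert len(batch.positives) == 7 == len(batch.negatives)
        assert not set(batch.positives) & set(batch.negatives)
        assert len(set(batch.locus_indices)) == 7

    def test_degenerate_probability_always_sampled(self):
        loci = toy_weighted(n_loci=4, genes_per=2, probs=[1.0, 0.0])
        pool = [f"n{i}" for i in range(10)]
        for seed in range(5):
            batch = sample_batch(loci, pool, 1.0, np.random.default_rng(seed))
            assert all(g.endswith("_g0") for g in batch.positives)

    def test_small_pool_rejected(self):
        loci = toy_weighted(n_loci=10)
        with pytest.raises(ValueError, match="pool"):
            sample_batch(loci, ["n0"], 0.7, np.random.default_rng(0))

    def test_empirical_sampling_frequency(self):
        """A gene with probability 0.8 is drawn ~80% of the time."""
        loci = toy_weighted(n_loci=1, genes_per=2, probs=[0.8, 0.2])
        pool = ["n0", "n1"]
        rng = np.random.default_rng(42)
        hits = sum(
            sample_batch(loci, pool, 1.0, rng).positives[0].endswith("_g0")
            for _ in range(10_000)
        )
        assert 0.78 <= hits / 10_000 <= 0.82


def small_features(loci, pool, rng, planted_for=None):
    ids = [g for wl in loci for g in wl.gene_ids] + list(pool)
    X = (rng.random((len(ids), 12)) < 0.05).astype(np.uint8)
    if planted_for:
        for i, g in enumerate(ids):
            if g in planted_for:
                X[i, :4] = (rng.random(4) < 0.9).astype(np.uint8)
    return FeatureMatrix(ids, [f"F{j}" for j in range(12)], X)


class TestBoost:
    def test_zero_trees_predicts_f0(self):
        loci = toy_weighted(4)
        pool = [f"n{i}" for i in range(10)]
        fm = small_features(loci, pool, np.random.default_rng(0))
        model = boost(loci, fm, pool, 0, TrainingConfig(), np.random.default_rng(1))
        preds = model.predict(fm.rows(pool))
        assert np.allclose(preds, model.f0)

    def test_zero_shrinkage_keeps_f0(self):
        loci = toy_weighted(4)
        pool = [f"n{i}" for i in range(10)]
        fm = small_features(loci, pool, np.random.default_rng(0))
        cfg = TrainingConfig(shrinkage=0.0)
        model = boost(loci, fm, pool, 10, cfg, np.random.default_rng(1))
        assert np.allclose(model.predict(fm.rows(pool)), model.f0)

    def test_greedy_step_never_increases_batch_loss(self):
        loci = toy_weighted(6)
        pool = [f"n{i}" for i in range(20)]
        fm = small_features(loci, pool, np.random.default_rng(2))
        model = boost(loci, fm, pool, 15, TrainingConfig(), np.random.default_rng(3))
        assert model.train_log, "train log should record each tree"
        for pre, post in model.train_log:
            assert post <= pre + 1e-9

    def test_separates_planted_signal(self):
        rng = np.random.default_rng(7)
        loci = toy_weighted(10, genes_per=2, probs=[1.0, 0.0])
        causal = {wl.gene_ids[0] for wl in loci}
        pool = [f"n{i}" for i in range(40)]
        fm = small_features(loci, pool, rng, planted_for=causal)
        model = boost(loci, fm, pool, 60, TrainingConfig(), rng)
        s_causal = np.median(model.predict(fm.rows(sorted(causal))))
        s_neg = np.median(model.predict(fm.rows(pool)))
        assert s_causal > s_neg


class TestPredictLogOdds:
    FM = FeatureMatrix(["a"], ["f"], [[0]])

    def test_midpoint_is_zero(self):
        m = BoostedModel(f0=0.5, shrinkage=0.1)
        assert predict_log_odds(m, self.FM.rows(["a"]))[0] == pytest.approx(0.0)

    def test_clamp_at_epsilon(self):
        m = BoostedModel(f0=1.7, shrinkage=0.1)
        v = predict_log_odds(m, self.FM.rows(["a"]), epsilon=1e-3)[0]
        assert v == pytest.approx(math.log(0.999 / 0.001), abs=1e-6)
        assert v == pytest.approx(6.9068, abs=1e-3)

    def test_monotone_in_f(self):
        for f1, f2 in [(0.9, 0.2), (0.51, 0.5), (2.0, 0.99)]:
            m1 = BoostedModel(f0=f1, shrinkage=0.0)
            m2 = BoostedModel(f0=f2, shrinkage=0.0)
            x = self.FM.rows(["a"])
            assert predict_log_odds(m1, x)[0] >= predict_log_odds(m2, x)[0]


class TestBurnin:
    def test_worked_tally_example(self):
        """Initial {5,5,0} with increments {12,6,2}: tally 30, cutoff 7.5,
        so exactly the two genes above it survive."""
        totals = {"A": 5 + 12, "B": 5 + 6, "C": 0 + 2}
        assert apply_burnin_filter(totals, 0.25) == {"A", "B"}

    def test_single_gene_locus_always_retained(self):
        assert apply_burnin_filter({"A": 0}, 0.25) == {"A"}

    def test_empty_filter_keeps_top_gene(self):
        # 4 equal genes at exactly 25% each: none is strictly above the
        # cutoff, so the filter would empty the locus; the top (lowest-id
        # on ties) gene is retained
        totals = {"D": 5, "C": 5, "B": 5, "A": 5}
        assert apply_burnin_filter(totals, 0.25) == {"A"}

    def test_refined_probabilities(self):
        rng = np.random.default_rng(9)
        loci = toy_weighted(8, genes_per=4)
        pool = [f"n{i}" for i in range(30)]
        fm = small_features(loci, pool, rng)
        cfg = TrainingConfig(n_burnin_trees=10)
        refined = burnin_refine(loci, fm, pool, cfg, rng)
        assert len(refined) == len(loci)
        for wl in refined:
            p = np.array([wl.probabilities[g] for g in wl.gene_ids])
            assert abs(p.sum() - 1.0) < 1e-9
            assert (p >= 0).all()
            assert (p > 0).sum() >= 1


class TestCrossValidate:
    def cv_inputs(self, small_trait, small_loci):
        universe = [g.gene_id for g in small_trait.genome]
        ev = evidence_sets_for_trait(small_loci, small_trait.collections, universe)
        gbi = {g.gene_id: g for g in small_trait.genome}
        weighted = weigh_loci(small_loci, gbi, ev["omim"], ev["go"], ev["mpd"])
        return weighted, universe

    def test_partition_covers_each_locus_once_per_round(self, small_trait, small_loci):
        weighted, universe = self.cv_inputs(small_trait, small_loci)
        cfg = TrainingConfig(n_rounds=2, n_main_trees=10, n_burnin_trees=5, seed=4)
        res = cross_validate(weighted, small_trait.features, universe, cfg)
        for folds in res.fold_assignments:
            flat = sorted(i for f in folds for i in f)
            assert flat == list(range(len(weighted)))

    def test_bit_reproducible(self, small_trait, small_loci):
        weighted, universe = self.cv_inputs(small_trait, small_loci)
        cfg = TrainingConfig(n_rounds=1, n_main_trees=8, n_burnin_trees=4, seed=7)
        a = cross_validate(weighted, small_trait.features, universe, cfg)
        b = cross_validate(weighted, small_trait.features, universe, cfg)
        assert a.scores.equals(b.scores)

    def test_all_genes_scored_finite(self, small_trait, small_loci):
        weighted, universe = self.cv_inputs(small_trait, small_loci)
        cfg = TrainingConfig(n_rounds=1, n_main_trees=8, n_burnin_trees=4, seed=7)
        res = cross_validate(weighted, small_trait.features, universe, cfg)
        assert list(res.scores.index) == universe
        assert np.isfinite(res.scores.to_numpy()).all()

    def test_mendelian_mode_builds_60_trees_no_burnin(self, small_trait):
        universe = [g.gene_id for g in small_trait.genome]
        positives = universe[:12]
        loci = mendelian_loci(positives)
        cfg = TrainingConfig(mode="mendelian", n_rounds=1, seed=3)
        res = cross_validate(loci, small_trait.features, universe, cfg)
        assert all(n == 60 for fold in res.trees_per_fold for n in fold)

    def test_too_few_loci_rejected(self, small_trait):
        loci = mendelian_loci(["G00001", "G00002"])
        cfg = TrainingConfig(mode="mendelian", n_rounds=1, seed=0)
        with pytest.raises(ValueError, match="loci"):
            cross_validate(loci, small_trait.features,
                           [g.gene_id for g in small_trait.genome], cfg)


class TestFeatureMatrix:
    def test_missing_gene_imputes_zero(self):
        fm = FeatureMatrix(["a", "b"], ["f1", "f2"], [[1, 0], [0, 1]])
        rows = fm.rows(["b", "ghost"])
        assert rows.tolist() == [[0, 1], [0, 0]]

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            FeatureMatrix(["a"], ["f"], [[2]])

    def test_from_triplets(self):
        fm = FeatureMatrix.from_triplets(
            [("a", "f2", 1), ("b", "f1", 1)], ["a", "b"], ["f1", "f2"]
        )
        assert fm.X.tolist() == [[0, 1], [1, 0]]

    def test_model_json_roundtrip(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(20, 5))
        r = rng.normal(size=20)
        tree = fit_lad_tree(X, r, 4)
        m = BoostedModel(f0=0.5, shrinkage=0.1, trees=[tree])
        m2 = BoostedModel.from_dict(m.to_dict())
        assert np.allclose(m.predict(X), m2.predict(X))
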