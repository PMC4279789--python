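# locusboost

Disease-gene prioritization at GWAS loci with prior-weighted stochastic
gradient boosting.

A genome-wide association study reports tag SNPs, not genes: each
association signal marks a block of correlated variants that typically
spans several genes, any of which could be the causal one. `locusboost`
ranks those candidates. It maps each tag SNP to a candidate-gene locus,
assigns each candidate a prior-evidence score, trains an adapted
gradient-boosting classifier on binary genomic features (binding-site
counts, expression-percentile indicators, protein domains, ...), and
emits a cross-validated log-odds of disease association for every gene
in the genome — including genes never seen at any locus. It is written
for statistical geneticists triaging GWAS hits, and for anyone
prioritizing candidate genes from linkage peaks or filtered sequencing
variants.

## The method

**Locus mapping.** A tag SNP's interval spans all partner SNPs with
r² ≥ 0.5, extends to the nearest flanking recombination hotspots, and
adds a 250 kb flank. Genes with a TSS inside the interval (or whose
body contains the SNP) are its candidates; an empty locus retries once
with a 50 kb widening.

**Prior weighting.** At a multi-gene locus each gene scores
5 points for a TSS within 50 kb of the tag SNP plus 5 per evidence
source — an OMIM-like Mendelian catalogue and enriched GO-like and
mouse-phenotype-like terms (one-sided hypergeometric test,
Benjamini–Hochberg adjusted p < 0.05, log₁₀ odds > 1) — for a maximum
of 20; the sole gene of a single-gene locus scores 1. Scores become
per-locus sampling probabilities (total 1 per locus); genes scoring
≥ 10 are flagged *likely positives* for evaluation.

**Boosting.** The classifier is an additive expansion
F(x) = f₀ + ν·Σₘ Tₘ(x) of 60 four-leaf LAD regression trees (absolute
loss; leaf values are medians of residuals; shrinkage ν = 0.1). Because
the positive label at a locus is uncertain, each tree draws one positive
per locus from 70% of loci according to the locus probabilities, with
matched negatives from genes outside all loci. A 20-tree burn-in phase
first refines the candidates: after each tree the top-scoring gene at
every locus earns +1 on a tally, and only genes holding > 25% of their
locus tally keep nonzero sampling probability (burn-in trees are then
discarded). Training runs as six rounds of eight-fold cross-validation
over loci (over genes, without burn-in, in Mendelian mode), so every
gene's score comes from models that never trained on it. The reported
score is logit(clamp(F(x), ε, 1−ε)).

**Evaluation.** AUROC (midrank Mann–Whitney), precision at fixed recall
with a binomial tail p, a within-locus rank permutation test (likely
positive in the top 3 — top 2 for 3-gene loci, top 1 for 2-gene loci),
an empirical top-score-at-locus null, and Fisher-style gene-set
enrichment over a fixed universe.

**Motif features.** PWM scanning under an entropy-weighted motif match
score, MMS = Σⱼ wⱼ log₂(f_{b(j)j}/p_{b(j)}) / Σⱼ wⱼ with
wⱼ = 2 + Σ_b f_bj log₂ f_bj; per-motif hit thresholds from a
three-component Gaussian mixture fitted by EM; hit-to-gene count
features (≥1, >1, >2, >3 copies) and 75th/90th/99th-percentile
indicators.

A synthetic-data module generates genomes, traits, LD tables, hotspots,
evidence sets and feature matrices with planted causal structure, so the
whole stack is testable end-to-end without any downloads.

## Worked example

```python
import numpy as np
from locusboost import (SimulationConfig, TrainingConfig, make_genome,
                        make_trait, prioritize)

sim = SimulationConfig()          # 2,000 genes, 15 loci, 10 planted features
rng = np.random.default_rng(sim.seed)
genome = make_genome(sim, rng)
trait = make_trait(genome, sim, rng)
loci = trait.build_loci()

cv, weighted, report = prioritize(
    loci, genome, trait.collections, trait.features,
    TrainingConfig(seed=1),
)
print(f"likely positives: {report['n_likely_positives']}")
print(f"AUROC vs likely positives: {report['auroc']:.3f}")
print(f"precision at {report['recall_level']:.0%} recall: "
      f"{report['precision_at_recall']:.2f} (binomial p = {report['binom_p']:.2e})")
print(f"top-k permutation p: {report['topk_p']:.2e}")
```

prints (about 10 s on one CPU):

```
likely positives: 14
AUROC vs likely positives: 0.964
precision at 20% recall: 1.00 (binomial p = 3.43e-07)
top-k permutation p: 1.00e-04
```

The 14 likely positives are the planted causal genes that received
enough prior evidence; an AUROC of 0.964 means a random likely positive
outranks a random other gene 96% of the time; the permutation p says a
likely positive lands in its locus's top ranks far more often than
uniformly permuted ranks would allow. Ranking the cross-validated
scores within each locus recovers the planted causal gene at the top of
14 of the 15 loci.

The same pipeline is available from the shell:

```sh
locusboost simulate --out data/ --seed 7
locusboost map-loci --annotation data/annotation.tsv --tags data/tags.tsv \
    --ld data/ld.tsv --hotspots data/hotspots.bed --out-bed data/loci.bed
locusboost prioritize --annotation data/annotation.tsv --loci-bed data/loci.bed \
    --tags data/tags.tsv --omim data/omim.gmt --go data/go.gmt --mpd data/mpd.gmt \
    --features data/features.tsv --feature-genes data/genes.txt \
    --feature-cols data/columns.txt --out-scores scores.tsv --out-report report.json
```

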