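# Methods

## Model and assumptions

`locusboost` treats disease-gene prioritization as a weakly supervised
binary classification problem. The units are genes; the labels are
uncertain: a GWAS locus asserts that *one* of its member genes is causal
without saying which. The model assumes that

* causal genes for a trait share binary genomic features (binding-site
  profiles, expression patterns, domain content) that distinguish them
  from random genes, so a classifier trained on sampled locus genes vs
  non-locus genes can transfer across loci;
* prior evidence (proximity to the index variant, Mendelian-disease
  catalogues, enriched ontology terms) is informative about which locus
  gene is causal, but noisy — it sets the *sampling distribution* of
  positive training examples rather than fixing the labels;
* genes outside every locus of the trait are overwhelmingly
  non-causal, so they can serve as the negative pool.

The classifier is gradient boosting under absolute (L1) loss on 0/1
targets: F(x) = f₀ + ν·Σ Tₘ(x), where f₀ is the median of the first
batch's targets (0.5 for the balanced batches used here), each Tₘ is a
four-leaf regression tree grown best-first on binary features with leaf
values equal to medians of residuals, and ν is the shrinkage. L1 loss
makes each tree chase the examples the current ensemble classifies
worst while staying robust to the label noise inherent in sampled
positives. The final per-gene score is the logit of F(x) clamped to
[ε, 1−ε].

## Pipeline stages and parameters

All coordinates are 0-based half-open (BED convention).

| stage | parameter | default | units | rationale |
|---|---|---|---|---|
| locus mapping | `r2_min` | 0.5 | r² | LD-block membership; boundary inclusive |
| | `flank_bp` | 250,000 | bp | distal-enhancer reach beyond the hotspot-bounded block |
| | `fallback_bp` | 50,000 | bp | one-shot widening of an empty locus |
| weighting | `evidence_pts` | 5 | points | per evidence source; deliberately unoptimized relative weights |
| | `proximity_bp` | 50,000 | bp | TSS-to-SNP distance for the proximity prior |
| | `likely_positive_min` | 10 | points | two independent lines of evidence |
| | `adj_p_max`, `lod_min` | 0.05, 1.0 | — | term selection: BH-adjusted p and log₁₀ sample odds ratio |
| boosting | `n_rounds` × `n_folds` | 6 × 8 | — | cross-validation over loci (GWA) or genes (Mendelian) |
| | `n_main_trees` | 60 | trees | the scored expansion |
| | `n_burnin_trees` | 20 | trees | candidate refinement only; discarded afterwards |
| | `n_leaves` | 4 | leaves | three split points per tree |
| | `locus_fraction` | 0.7 | — | loci sampled per tree |
| | `burnin_keep_fraction` | 0.25 | — | tally share a gene must exceed to stay a positive candidate |
| | `shrinkage` | 0.1 | — | conventional small-step value; recorded in every run log |
| | `epsilon` | 1e-3 | — | clamp for the logit transform |
| motifs | `pseudocount` | 0.01 | — | per-cell before column renormalization; prevents log 0 |

The shrinkage default of 0.1 is the field's conventional small-step
choice for expansions of this length; it is configurable and every run
logs it.

## Design choices where the design was open

* **Loss vs log-odds output.** Boosting is implemented as LAD regression
  on 0/1 targets (initial constant = median, leaf medians of residuals),
  with the log-odds obtained by a final clamp-and-logit transform of
  F(x). This keeps the tree-growing criterion exactly absolute loss
  while still emitting a log-odds score per gene.
* **Negative pool.** All annotated genes belonging to no locus of the
  trait (GWA) or absent from the positive list (Mendelian). Genes at
  several loci are excluded from the pool and scored by averaging the
  fold models that held out their loci.
* **Burn-in accounting.** The +1 increment goes to the top-scoring gene
  of *every* training locus after every tree (not only sampled loci).
  The tally compared against the 25% cutoff includes the initial prior
  scores (`tally_includes_initial=False` switches to increments only).
  Burn-in trees are discarded; the 60 main trees are trained fresh from
  the refined sampling weights. If the filter would empty a locus, the
  top-tally gene is retained so the locus stays usable; single-gene
  loci are always retained.
* **All-zero loci** get uniform sampling probabilities, so every locus
  can contribute a positive example.
* **Ties** break deterministically everywhere: lowest feature index in
  split search, lexicographically smallest gene id for top-gene and
  ranking ties. With a fixed seed the whole cross-validation is
  bit-reproducible.
* **Enrichment internals.** Term selection uses a one-sided
  hypergeometric test with BH adjustment and the log₁₀ sample odds
  ratio (0.5 continuity correction on zero cells). The log-odds base
  follows the LOD convention of gene-set enrichment servers; note that
  at a fixed odds-ratio cutoff small universes are penalized — a term
  needs a proportionally larger overlap to clear `lod_min` when the
  universe is only a few hundred genes.
* **Hotspot semantics.** "Next hotspot" means the nearest hotspot
  position at-or-beyond each interval end; interior hotspots are
  ignored and a missing flanking hotspot leaves that end unchanged.
* **Empirical p conventions.** The within-locus permutation test uses
  the +1-corrected form (#null ≥ observed + 1)/(n_perm + 1), so it never
  reports exactly 0. The top-score-at-locus null reports the plain
  fraction of iterations (its definition is explicitly a fraction), and
  draws scores without replacement within an iteration because a
  locus's genes are distinct; a with-replacement mode exists for
  closed-form checking (P(max ≥ x) = 1 − F(x)ⁿ).
* **MMS sign and weights.** Higher MMS = better match, so that
  thresholding on the highest-mean mixture component selects strong
  matches; a `paper_sign` flag emits the negated convention. Position
  weights default to the Shannon information content
  wⱼ = 2 + Σ_b f_bj log₂ f_bj ∈ [0, 2]; a `literal` variant without the
  f_bj multiplier is retained for comparison. Overlapping scan hits are
  all kept; a hit is attributed to every gene whose body ± window
  contains its start coordinate.
* **Mixture threshold.** 1-D EM with k-means++ initialization, best of
  20 restarts, tolerance 1e-8, ≤ 500 iterations, variance floored at
  1e-6 of the data variance. Components are sorted by mean; the
  threshold is the lowest score MAP-assigned to the highest-mean
  component. The log-likelihood is asserted non-decreasing across
  iterations. At least 3k distinct values are required.
* **Quantile features** use linearly interpolated quantiles and strict
  `>` membership, so a constant sample yields all-zero columns.
* **Missing feature rows** impute to all-zero (absence of evidence).

## What the synthetic generator emulates — and what it does not

`simulate` builds a genome of head-to-tail genes (default 2,000 genes,
one chromosome, mean spacing 100 kb with ±50% jitter — roughly the
human genome's gene density) and, per trait, 15 non-overlapping loci.
Each locus is anchored on one causal gene: the tag SNP falls within
±40 kb of the causal TSS (inside the proximity-prior window, mirroring
the regulatory-reach reasoning behind that prior), LD partners with
r² ∈ [0.5, 1] pin a block of up to ~200 kb per side (decoy partners
with r² ∈ [0, 0.45] sit outside), and hotspots lie just outside the
block edges, so the mapping pipeline recovers the intended 4–10 member
genes exactly; the generator asserts this. Causal genes carry each of
10 planted features at rate q_causal = 0.8 versus a background rate of
0.05; half of the causal genes (per source, independently) appear in a
focused disease term of each evidence collection, alongside 8 unrelated
genes and five decoy terms. The truth never enters the features except
through the Bernoulli rates.

This emulates the *structure* the method assumes — shared features among
causal genes, partial prior knowledge, LD-delimited loci — but not real
data's difficulties: LD here is block-shaped rather than
population-genetic, features are independent Bernoulli rather than
correlated annotation tracks, every locus contains its causal gene, and
the evidence sets are never wrong (only incomplete). Passing the
recovery tests therefore shows the machinery is correct and can extract
a planted signal of realistic strength; it does not certify performance
on real traits, where feature relevance and prior quality are far more
heterogeneous.

## Problem sizes used in the test suite

The recovery experiments run the full 6 × 8-fold cross-validation on
the default scenario (2,000 genes × 200 features, 15 loci, ~10 s); the
null-calibration experiment repeats it with q_causal = q_background.
Burn-in survival statistics pool 50 replicates of a reduced scenario
(800 genes, 8 loci, 100 features) — burn-in behaviour depends on
per-locus tallies, not universe size, so the reduction does not change
what is being measured. Oracle-equivalence suites use instances small
enough for exhaustive enumeration (12-example batches, ≤ 14-gene
universes, 3-mer motifs).

## Known limitations

* Evidence terms are matched to a trait by enrichment of its locus
  genes only; no ontology-graph propagation or trait-to-term text
  matching is attempted.
* The burn-in tally semantics ("score of the gene at each locus") are
  implemented per training locus per tree; alternative readings (only
  sampled loci) would slow refinement but are not exposed.
* LD blocks are taken from a pairwise table; the package never computes
  LD from genotypes, merges overlapping loci, or lifts coordinates
  between assemblies.
* The motif module takes empirical score pools for threshold fitting as
  given; it does not model DNase accessibility, conservation filtering,
  or ChIP peak calling.
* With very small universes the log-odds selection rule for evidence
  terms is conservative (see above); likely positives may then be empty
  and rank-based evaluation is skipped with a warning.
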