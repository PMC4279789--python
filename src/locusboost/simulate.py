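"""Synthetic genomes and traits with planted causal structure.

Everything the prioritization pipeline consumes — gene annotation, tag
SNPs, LD tables, recombination hotspots, evidence gene sets and a binary
feature matrix — is generated here with a known ground truth, so the full
locus-mapping / weighting / boosting / evaluation stack can be exercised
end-to-end and its recovery of the planted causal genes measured.

Per trait, each locus is built around one causal gene: the tag SNP sits
within 40 kb of the causal TSS (inside the 50 kb proximity-prior window),
LD partners with r^2 in [0.5, 1] span up to ~200 kb per side (plus decoy
partners below r^2 0.45 outside the block), and hotspots sit just outside
the LD block edges, so the mapping pipeline deterministically recovers
the intended member genes.  Causal genes carry each of the planted
features with probability ``q_causal``; every other (gene, feature) cell
is background at ``q_background``.  A configurable fraction of causal
genes is listed in each evidence gene-set collection, emulating partial
prior knowledge.  The generator never writes the truth into the features
except through those Bernoulli rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .boosting import FeatureMatrix
from .loci import (
    GeneAnnotation,
    LDPair,
    LocusInterval,
    LocusParams,
    TagSNP,
    build_locus,
)
from .weighting import GeneSetCollection

__all__ = ["SimulationConfig", "SyntheticTruth", "SyntheticTrait",
           "make_genome", "make_trait"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the default synthetic scenario."""

    n_chroms: int = 1
    n_genes: int = 2000
    gene_spacing_bp: int = 100_000
    n_loci: int = 15
    genes_per_locus: tuple[int, int] = (4, 10)
    n_features: int = 200
    n_planted: int = 10
    q_causal: float = 0.8
    q_background: float = 0.05
    evidence_coverage: float = 0.5
    trait: str = "synthetic_trait"
    seed: int = 20141203

    def __post_init__(self) -> None:
        if self.n_planted > self.n_features:
            raise ValueError("n_planted must be <= n_features")
        for q in (self.q_causal, self.q_background, self.evidence_coverage):
            if not (0.0 <= q <= 1.0):
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    causal_gene: dict[str, str]  # tag rsid -> gene id
    planted_feature_ids: list[str]
    q_causal: float
    q_background: float
    seed: int


@dataclass
class SyntheticTrait:
    """A complete synthetic input bundle plus its ground truth."""

    config: SimulationConfig
    genome: list[GeneAnnotation]
    tags: list[TagSNP]
    ld_pairs: list[LDPair]
    hotspots: dict[str, list[int]]
    collections: dict[str, GeneSetCollection]
    features: FeatureMatrix
    truth: SyntheticTruth
    intended_members: dict[str, list[str]] = field(default_factory=dict)

    def build_loci(self, params: LocusParams = LocusParams()) -> list[LocusInterval]:
        return [
            build_locus(
                tag,
                self.ld_pairs,
                self.hotspots.get(tag.chrom, []),
                self.genome,
                params,
            )
            for tag in self.tags
        ]

    def write(self, outdir: str | Path) -> None:
        from . import io as lio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lio.write_gene_annotation(self.genome, outdir / "annotation.tsv")
        lio.write_tag_snps(self.tags, outdir / "tags.tsv")
        lio.write_ld_table(self.ld_pairs, outdir / "ld.tsv")
        lio.write_hotspots(self.hotspots, outdir / "hotspots.bed")
        for src, coll in self.collections.items():
            lio.write_gmt(coll, outdir / f"{src}.gmt")
        lio.write_feature_triplets(self.features, outdir / "features.tsv",
                                   outdir / "genes.txt", outdir / "columns.txt")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(asdict(self.truth), fh, indent=1, sort_keys=True)


def make_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> list[GeneAnnotation]:
    """Genes laid head-to-tail with jittered spacing, never overlapping."""
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    genes = []
    gid = 0
    for ci, n in enumerate(per_chrom):
        pos = int(rng.integers(10_000, 60_000))
        for _ in range(n):
            body = int(rng.integers(2_000, 40_000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneAnnotation(
                    gene_id=f"G{gid:05d}",
                    chrom=f"chr{ci + 1}",
                    tx_start=pos,
                    tx_end=pos + body,
                    strand=strand,
                )
            )
            gid += 1
            spacing = config.gene_spacing_bp * rng.uniform(0.5, 1.5)
            pos += max(body + 1_000, int(spacing))
    return genes


def _pick_anchors(
    chrom_sizes: dict[str, int], n_loci: int, min_gap: int, rng: np.random.Generator
) -> list[tuple[str, int]]:
    candidates = [
        (chrom, i)
        for chrom, n in chrom_sizes.items()
        for i in range(min_gap, n - min_gap)
    ]
    order = rng.permutation(len(candidates))
    picked: list[tuple[str, int]] = []
    for oi in order:
        chrom, i = candidates[oi]
        if all(c != chrom or abs(i - j) >= min_gap for c, j in picked):
            picked.append((chrom, i))
            if len(picked) == n_loci:
                picked.sort()
                return picked
    raise ValueError("infeasible packing: cannot place that many loci")


def make_trait(
    genome: Sequence[GeneAnnotation],
    config: SimulationConfig,
    rng: np.random.Generator,
    locus_params: LocusParams = LocusParams(),
) -> SyntheticTrait:
    """Generate a trait's full input bundle over an existing genome."""
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in sorted(genome, key=lambda g: (g.chrom, g.tss, g.gene_id)):
        by_chrom.setdefault(g.chrom, []).append(g)
    min_gap = max(
        12, int(3 * locus_params.flank_bp / config.gene_spacing_bp) + config.genes_per_locus[1]
    )
    anchors = _pick_anchors(
        {c: len(v) for c, v in by_chrom.items()}, config.n_loci, min_gap, rng
    )

    tags: list[TagSNP] = []
    ld_pairs: list[LDPair] = []
    hotspots: dict[str, set[int]] = {c: set() for c in by_chrom}
    causal: dict[str, str] = {}
    intended: dict[str, list[str]] = {}
    claimed: set[str] = set()
    lo_min, lo_max = config.genes_per_locus

    for li, (chrom, ai) in enumerate(anchors):
        chrom_genes = by_chrom[chrom]
        anchor = chrom_genes[ai]
        rsid = f"rs{li + 1:05d}"
        ok = False
        for _ in range(50):
            tag_pos = int(anchor.tss + rng.integers(-40_000, 40_001))
            span_l = int(rng.integers(50_000, 200_001))
            span_r = int(rng.integers(50_000, 200_001))
            block_lo, block_hi = tag_pos - span_l, tag_pos + span_r
            hl = block_lo - int(rng.integers(0, 30_001))
            hr = block_hi + 1 + int(rng.integers(0, 30_001))
            start = hl - locus_params.flank_bp
            end = hr + locus_params.flank_bp
            if start < 0:
                continue
            tag = TagSNP(rsid=rsid, chrom=chrom, pos=tag_pos, trait=config.trait)
            members = [
                g.gene_id
                for g in chrom_genes
                if start <= g.tss < end or g.tx_start <= tag_pos < g.tx_end
            ]
            if not (lo_min <= len(members) <= lo_max):
                continue
            if anchor.gene_id not in members or claimed & set(members):
                continue
            # qualifying LD partners pin the block edges; decoys sit outside
            n_extra = int(rng.integers(1, 5))
            partner_pos = [block_lo, block_hi] + [
                int(rng.integers(block_lo, block_hi + 1)) for _ in range(n_extra)
            ]
            pairs = [
                LDPair(rsid, f"{rsid}_p{j}", p, float(rng.uniform(0.5, 1.0)), chrom)
                for j, p in enumerate(partner_pos)
            ]
            for side, base in (("l", block_lo), ("r", block_hi)):
                decoy = base + (-1 if side == "l" else 1) * int(
                    rng.integers(60_000, 150_001)
                )
                if decoy >= 0:
                    pairs.append(
                        LDPair(rsid, f"{rsid}_d{side}", decoy,
                               float(rng.uniform(0.0, 0.45)), chrom)
                    )
            tags.append(tag)
            ld_pairs.extend(pairs)
            hotspots[chrom].update((hl, hr))
            causal[rsid] = anchor.gene_id
            intended[rsid] = members
            claimed |= set(members)
            ok = True
            break
        if not ok:
            raise ValueError(f"infeasible packing: could not place locus {li}")

    hotspot_lists = {c: sorted(v) for c, v in hotspots.items()}
    trait = _finish_trait(
        config, list(genome), tags, ld_pairs, hotspot_lists, causal, intended, rng
    )
    # construction guarantee: the mapping pipeline recovers the intent
    for tag, locus in zip(trait.tags, trait.build_loci(locus_params)):
        if locus.member_genes != trait.intended_members[tag.rsid]:
            raise AssertionError(
                f"locus {tag.rsid}: mapped members diverge from construction"
            )
    return trait


def _finish_trait(
    config: SimulationConfig,
    genome: list[GeneAnnotation],
    tags: list[TagSNP],
    ld_pairs: list[LDPair],
    hotspots: dict[str, list[int]],
    causal: dict[str, str],
    intended: dict[str, list[str]],
    rng: np.random.Generator,
) -> SyntheticTrait:
    gene_ids = [g.gene_id for g in genome]
    causal_ids = sorted(set(causal.values()))
    locus_genes = {g for members in intended.values() for g in members}
    background_ids = [g for g in gene_ids if g not in locus_genes]

    # evidence collections: one trait-relevant term per source covering a
    # fraction of causal genes (plus unrelated genes), and decoy terms
    collections: dict[str, GeneSetCollection] = {}
    n_cover = int(round(config.evidence_coverage * len(causal_ids)))
    for src in ("omim", "go", "mpd"):
        covered = list(
            rng.choice(causal_ids, size=min(n_cover, len(causal_ids)), replace=False)
        ) if n_cover else []
        # a focused disease term: covered causal genes plus a handful of
        # unrelated genes, tight enough to register as enriched (LOD > 1)
        filler = list(rng.choice(background_ids, size=8, replace=False))
        sets = {f"{src.upper()}:SYN0001": frozenset(covered + filler)}
        names = {f"{src.upper()}:SYN0001": f"synthetic {src} disease term"}
        for d in range(1, 6):
            size = int(rng.integers(20, 51))
            decoy = frozenset(rng.choice(background_ids, size=size, replace=False))
            sets[f"{src.upper()}:SYN{d + 1:04d}"] = decoy
            names[f"{src.upper()}:SYN{d + 1:04d}"] = f"synthetic {src} decoy {d}"
        collections[src] = GeneSetCollection(source=src, sets=sets, names=names)

    feature_ids = [f"F{j:04d}" for j in range(config.n_features)]
    planted_idx = np.sort(
        rng.choice(config.n_features, size=config.n_planted, replace=False)
    )
    X = (rng.random((len(gene_ids), config.n_features)) < config.q_background)
    causal_rows = [gene_ids.index(g) for g in causal_ids]
    X[np.ix_(causal_rows, planted_idx)] = (
        rng.random((len(causal_rows), config.n_planted)) < config.q_causal
    )
    features = FeatureMatrix(gene_ids, feature_ids, X.astype(np.uint8))

    truth = SyntheticTruth(
        causal_gene=dict(causal),
        planted_feature_ids=[feature_ids[j] for j in planted_idx],
        q_causal=config.q_causal,
        q_background=config.q_background,
        seed=config.seed,
    )
    return SyntheticTrait(
        config=config,
        genome=genome,
        tags=tags,
        ld_pairs=ld_pairs,
        hotspots=hotspots,
        collections=collections,
        features=features,
        truth=truth,
        intended_members=intended,
    )
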