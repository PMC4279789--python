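"""Mapping of GWAS tag SNPs to candidate-gene loci.

A reported association signal ("tag SNP") is a proxy for an unknown causal
variant somewhere in the surrounding block of correlated variants.  The
locus interval for a tag SNP is built in four steps:

1. span the tag and every partner SNP in strong linkage disequilibrium
   (r^2 >= ``r2_min``, default 0.5);
2. extend each end outward to the nearest flanking recombination hotspot;
3. add a fixed flank (default 250 kb) to allow for distal regulation;
4. collect genes whose transcription start site (TSS) falls inside the
   interval, plus any gene whose body contains the tag SNP itself; if the
   locus is empty, retry once with the interval widened by ``fallback_bp``
   (default 50 kb) per side.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "GeneAnnotation",
    "TagSNP",
    "LDPair",
    "LocusInterval",
    "LocusParams",
    "ld_block",
    "extend_to_hotspots",
    "extend_flank",
    "assign_genes",
    "build_locus",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene model: transcribed interval, strand and TSS.

    ``tss`` may be omitted, in which case it is derived from the strand
    (``tx_start`` on '+', ``tx_end - 1`` on '-').
    """

    gene_id: str
    chrom: str
    tx_start: int
    tx_end: int
    strand: str = "+"
    tss: int | None = None

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError(
                f"{self.gene_id}: tx_start {self.tx_start} >= tx_end {self.tx_end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.tss is None:
            tss = self.tx_start if self.strand == "+" else self.tx_end - 1
            object.__setattr__(self, "tss", tss)
        if not (self.tx_start <= self.tss < self.tx_end):
            raise ValueError(f"{self.gene_id}: TSS {self.tss} outside gene body")


@dataclass(frozen=True)
class TagSNP:
    """A trait-associated index variant."""

    rsid: str
    chrom: str
    pos: int
    trait: str = ""
    assoc_p: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"{self.rsid}: negative position")


@dataclass(frozen=True)
class LDPair:
    """One row of a pairwise LD table: partner SNP position and r^2.

    ``rsid_a`` is the anchor (tag) SNP; ``pos_b`` locates the partner.
    ``chrom_b`` is optional and only used for consistency checking.
    """

    rsid_a: str
    rsid_b: str
    pos_b: int
    r2: float
    chrom_b: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"r2 {self.r2} outside [0, 1]")


@dataclass
class LocusInterval:
    """A tag SNP's genomic interval with its ordered member genes."""

    tag: TagSNP
    chrom: str
    start: int
    end: int
    member_genes: list[str] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return len(self.member_genes) == 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("locus interval must be non-empty")
        if not (self.start <= self.tag.pos < self.end):
            raise ValueError("tag SNP outside its locus interval")


@dataclass(frozen=True)
class LocusParams:
    """Tunables of the mapping pipeline (defaults as used throughout)."""

    r2_min: float = 0.5
    flank_bp: int = 250_000
    fallback_bp: int = 50_000
    chrom_len: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_min <= 1.0):
            raise ValueError("r2_min must be in (0, 1]")
        if self.flank_bp < 0 or self.fallback_bp < 0:
            raise ValueError("flank/fallback must be non-negative")


def ld_block(
    tag: TagSNP, ld: Iterable[LDPair], r2_min: float = 0.5
) -> tuple[int, int]:
    """Minimal interval covering the tag and all partners with r^2 >= r2_min.

    The r^2 boundary is inclusive.  With no qualifying partner the block is
    the single base at the tag position.  Partners recorded on a different
    chromosome are rejected.
    """
    lo = tag.pos
    hi = tag.pos
    for pair in ld:
        if pair.rsid_a != tag.rsid:
            continue
        if pair.chrom_b is not None and pair.chrom_b != tag.chrom:
            raise ValueError(
                f"LD partner {pair.rsid_b} on {pair.chrom_b} but tag "
                f"{tag.rsid} on {tag.chrom}"
            )
        if pair.r2 >= r2_min:
            lo = min(lo, pair.pos_b)
            hi = max(hi, pair.pos_b)
    return lo, hi + 1


def extend_to_hotspots(
    interval: tuple[int, int], hotspots: Sequence[int]
) -> tuple[int, int]:
    """Push interval ends out to the nearest flanking recombination hotspot.

    The start moves left to the nearest hotspot position <= start; the end
    moves right to the nearest hotspot position >= end.  Hotspots strictly
    inside the interval are ignored, and an end without a flanking hotspot
    is left unchanged.  ``hotspots`` must be sorted ascending.
    """
    start, end = interval
    i = bisect.bisect_right(hotspots, start)
    if i > 0:
        start = hotspots[i - 1]
    j = bisect.bisect_left(hotspots, end)
    if j < len(hotspots):
        end = hotspots[j]
    return start, end


def extend_flank(
    interval: tuple[int, int], flank_bp: int, chrom_len: int | None = None
) -> tuple[int, int]:
    """Add a symmetric flank, clipped to [0, chrom_len)."""
    start, end = interval
    start = max(0, start - flank_bp)
    end = end + flank_bp
    if chrom_len is not None:
        end = min(chrom_len, end)
    return start, end


def _genes_in(
    interval: tuple[int, int], tag: TagSNP, genes: Sequence[GeneAnnotation]
) -> list[GeneAnnotation]:
    start, end = interval
    hits = [
        g
        for g in genes
        if g.chrom == tag.chrom
        and (start <= g.tss < end or g.tx_start <= tag.pos < g.tx_end)
    ]
    hits.sort(key=lambda g: (g.tss, g.gene_id))
    return hits


def assign_genes(
    interval: tuple[int, int],
    tag: TagSNP,
    genes: Sequence[GeneAnnotation],
    fallback_bp: int = 50_000,
) -> LocusInterval:
    """Collect member genes for a locus interval.

    A gene is a member if its TSS lies in the interval or if the tag SNP
    falls within the gene body.  An empty locus is retried once with the
    interval widened by ``fallback_bp`` on each side; if still empty the
    locus is kept but flagged empty (excluded from training downstream).
    """
    members = _genes_in(interval, tag, genes)
    if not members and fallback_bp > 0:
        widened = (max(0, interval[0] - fallback_bp), interval[1] + fallback_bp)
        members = _genes_in(widened, tag, genes)
    return LocusInterval(
        tag=tag,
        chrom=tag.chrom,
        start=interval[0],
        end=interval[1],
        member_genes=[g.gene_id for g in members],
    )


def build_locus(
    tag: TagSNP,
    ld: Iterable[LDPair],
    hotspots: Sequence[int],
    genes: Sequence[GeneAnnotation],
    params: LocusParams = LocusParams(),
) -> LocusInterval:
    """Full mapping pipeline for one tag SNP (deterministic composition)."""
    block = ld_block(tag, ld, params.r2_min)
    block = extend_to_hotspots(block, hotspots)
    block = extend_flank(block, params.flank_bp, params.chrom_len)
    return assign_genes(block, tag, genes, params.fallback_bp)
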