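"""Readers and writers for the plain-text formats used across the package.

Coordinates are 0-based half-open everywhere (BED convention).  All
writers produce files their paired readers parse losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .boosting import BoostedModel, FeatureMatrix
from .loci import GeneAnnotation, LDPair, LocusInterval, TagSNP
from .motifs import PWM, MotifHit
from .weighting import GeneSetCollection, WeightedLocus

__all__ = [
    "read_gene_annotation", "write_gene_annotation",
    "read_tag_snps", "write_tag_snps",
    "read_ld_table", "write_ld_table",
    "read_hotspots", "write_hotspots",
    "read_gmt", "write_gmt",
    "read_feature_matrix_dense", "read_feature_triplets",
    "write_feature_triplets", "read_feature_mtx",
    "write_loci_bed", "read_loci_bed",
    "write_weighted_loci", "write_scores", "read_scores",
    "save_model", "load_model",
    "read_fasta", "read_pwms", "write_hits_bed",
]


def _err(path: str | Path, line_no: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{line_no}: {msg}")


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Gene annotation TSV: gene_id, chrom, tx_start, tx_end, strand[, tss].

    With no ``tss`` column (or with BED6 columns chrom/start/end/name/
    score/strand) the TSS is derived from the strand.
    """
    df = pd.read_csv(path, sep="\t")
    cols = set(df.columns)
    if {"gene_id", "chrom", "tx_start", "tx_end", "strand"} <= cols:
        pass
    elif len(df.columns) == 6 and df.columns[0].startswith(("#", "chr")):
        # BED6: chrom start end name score strand
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "tx_start", "tx_end", "gene_id", "score", "strand"],
        )
    else:
        raise _err(path, 1, f"unrecognized annotation header: {sorted(cols)}")
    genes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            genes.append(
                GeneAnnotation(
                    gene_id=str(row.gene_id),
                    chrom=str(row.chrom),
                    tx_start=int(row.tx_start),
                    tx_end=int(row.tx_end),
                    strand=str(row.strand),
                    tss=int(row.tss) if hasattr(row, "tss") else None,
                )
            )
        except (ValueError, TypeError) as e:
            raise _err(path, i, str(e)) from e
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise _err(path, 0, "duplicate gene ids")
    return genes


def write_gene_annotation(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            (g.gene_id, g.chrom, g.tx_start, g.tx_end, g.strand, g.tss)
            for g in genes
        ],
        columns=["gene_id", "chrom", "tx_start", "tx_end", "strand", "tss"],
    ).to_csv(path, sep="\t", index=False)


def read_tag_snps(path: str | Path) -> list[TagSNP]:
    """Tag SNP TSV: rsid, chrom, pos, trait[, assoc_p]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                TagSNP(
                    rsid=str(row.rsid), chrom=str(row.chrom), pos=int(row.pos),
                    trait=str(row.trait),
                    assoc_p=float(row.assoc_p) if hasattr(row, "assoc_p") else None,
                )
            )
        except (ValueError, TypeError) as e:
            raise _err(path, i, str(e)) from e
    return out


def write_tag_snps(tags: Sequence[TagSNP], path: str | Path) -> None:
    pd.DataFrame(
        [(t.rsid, t.chrom, t.pos, t.trait) for t in tags],
        columns=["rsid", "chrom", "pos", "trait"],
    ).to_csv(path, sep="\t", index=False)


def read_ld_table(path: str | Path) -> list[LDPair]:
    """Whitespace-delimited LD table; PLINK .ld dialect accepted.

    Requires columns SNP_A, SNP_B, BP_B, R2 (CHR_B honoured if present).
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"R2": str})
    need = {"SNP_A", "SNP_B", "BP_B", "R2"}
    if not need <= set(df.columns):
        raise _err(path, 1, f"LD table needs columns {sorted(need)}")
    has_chrom = "CHR_B" in df.columns
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                LDPair(
                    rsid_a=str(row.SNP_A), rsid_b=str(row.SNP_B),
                    pos_b=int(row.BP_B), r2=float(row.R2),
                    chrom_b=str(row.CHR_B) if has_chrom else None,
                )
            )
        except (ValueError, TypeError) as e:
            raise _err(path, i, str(e)) from e
    return out


def write_ld_table(pairs: Sequence[LDPair], path: str | Path) -> None:
    pd.DataFrame(
        [(p.chrom_b or ".", p.rsid_a, p.rsid_b, p.pos_b, p.r2) for p in pairs],
        columns=["CHR_B", "SNP_A", "SNP_B", "BP_B", "R2"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_hotspots(path: str | Path) -> dict[str, list[int]]:
    """BED3 of recombination hotspots; the start coordinate is the position."""
    out: dict[str, list[int]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise _err(path, i, "BED3 requires chrom, start, end")
            out.setdefault(parts[0], []).append(int(parts[1]))
    return {c: sorted(v) for c, v in out.items()}


def write_hotspots(hotspots: Mapping[str, Sequence[int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(hotspots):
            for pos in sorted(hotspots[chrom]):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")


def read_gmt(path: str | Path, source: str = "") -> GeneSetCollection:
    """GMT: term_id TAB description TAB gene TAB gene ..."""
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise _err(path, i, "GMT line needs term, description, >=1 gene")
            sets[parts[0]] = frozenset(p for p in parts[2:] if p)
            names[parts[0]] = parts[1]
    return GeneSetCollection(source=source or Path(path).stem, sets=sets, names=names)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\t{collection.names.get(term, term)}\t{genes}\n")


def read_feature_matrix_dense(path: str | Path) -> FeatureMatrix:
    """Dense TSV: first column gene ids, remaining columns binary features."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureMatrix(
        [str(g) for g in df.index], [str(c) for c in df.columns], df.to_numpy()
    )


def write_feature_triplets(
    fm: FeatureMatrix,
    path: str | Path,
    genes_path: str | Path,
    features_path: str | Path,
) -> None:
    """Sparse triplet TSV (gene, feature, 1) with sidecar id lists."""
    gi, fi = np.nonzero(fm.X)
    with open(path, "w") as fh:
        fh.write("gene_id\tfeature_id\tvalue\n")
        for g, f in zip(gi, fi):
            fh.write(f"{fm.gene_ids[g]}\t{fm.feature_ids[f]}\t1\n")
    Path(genes_path).write_text("\n".join(fm.gene_ids) + "\n")
    Path(features_path).write_text("\n".join(fm.feature_ids) + "\n")


def read_feature_triplets(
    path: str | Path,
    genes_path: str | Path | None = None,
    features_path: str | Path | None = None,
) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t")
    trips = [
        (str(r.gene_id), str(r.feature_id), int(r.value))
        for r in df.itertuples(index=False)
    ]
    gene_ids = (
        Path(genes_path).read_text().split() if genes_path else None
    )
    feature_ids = (
        Path(features_path).read_text().split() if features_path else None
    )
    return FeatureMatrix.from_triplets(trips, gene_ids, feature_ids)


def read_feature_mtx(
    path: str | Path, genes_path: str | Path, features_path: str | Path
) -> FeatureMatrix:
    """MatrixMarket sparse matrix with sidecar gene/feature id lists."""
    from scipy.io import mmread

    X = (mmread(path).toarray() != 0).astype(np.uint8)
    gene_ids = Path(genes_path).read_text().split()
    feature_ids = Path(features_path).read_text().split()
    return FeatureMatrix(gene_ids, feature_ids, X)


def write_loci_bed(loci: Sequence[LocusInterval], path: str | Path) -> None:
    """BED6+: chrom, start, end, tag rsid, n_genes, '.', comma-joined genes."""
    with open(path, "w") as fh:
        for L in loci:
            genes = ",".join(L.member_genes)
            fh.write(
                f"{L.chrom}\t{L.start}\t{L.end}\t{L.tag.rsid}\t"
                f"{len(L.member_genes)}\t.\t{genes}\n"
            )


def read_loci_bed(
    path: str | Path, tags: Mapping[str, TagSNP]
) -> list[LocusInterval]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 7:
                raise _err(path, i, "loci BED needs 7 columns")
            rsid = parts[3]
            if rsid not in tags:
                raise _err(path, i, f"unknown tag SNP {rsid}")
            out.append(
                LocusInterval(
                    tag=tags[rsid], chrom=parts[0],
                    start=int(parts[1]), end=int(parts[2]),
                    member_genes=[g for g in parts[6].split(",") if g],
                )
            )
    return out


def write_weighted_loci(weighted: Sequence[WeightedLocus], path: str | Path) -> None:
    rows = []
    for wl in weighted:
        for g in wl.gene_ids:
            s = wl.scores[g]
            rows.append(
                (
                    wl.locus.tag.rsid, g, s.proximity_pts, s.omim_pts,
                    s.go_pts, s.mpd_pts, s.total, wl.probabilities[g],
                    int(wl.likely_positive[g]),
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "locus", "gene", "proximity_pts", "omim_pts", "go_pts",
            "mpd_pts", "total", "probability", "likely_positive",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def save_model(model: BoostedModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def load_model(path: str | Path) -> BoostedModel:
    with open(path) as fh:
        return BoostedModel.from_dict(json.load(fh))


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_pwms(
    path: str | Path,
    fmt: str = "jaspar",
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.01,
) -> list[PWM]:
    """Parse JASPAR PFM or MEME-minimal motif files into PWM objects."""
    if fmt not in ("jaspar", "minimal"):
        raise ValueError(f"unsupported motif format {fmt!r}")
    out = []
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, fmt)
            for m in records:
                counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
                motif_id = getattr(m, "matrix_id", None) or m.name or "motif"
                out.append(
                    PWM.from_counts(
                        motif_id,
                        counts,
                        background=np.asarray(background, dtype=float),
                        pseudocount=pseudocount,
                    )
                )
        except Exception as e:
            raise ValueError(f"{path}: malformed PWM file ({e})") from e
    return out


def write_hits_bed(hits: Sequence[MotifHit], path: str | Path) -> None:
    """BED6 + raw MMS: score column is MMS x 100 clamped to [0, 1000]."""
    with open(path, "w") as fh:
        for h in hits:
            bed_score = int(min(1000, max(0, round(h.mms * 100))))
            fh.write(
                f"{h.seq_id}\t{h.pos}\t{h.pos + 1}\t.\t{bed_score}\t"
                f"{h.strand}\t{h.mms:.6g}\n"
            )
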