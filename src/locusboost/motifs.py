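"""Motif-derived binary genomic features.

Transcription-factor binding sites are predicted by scanning sequences
with position weight matrices under an entropy-weighted motif match score
(MMS): each position contributes the log2 ratio of the motif's frequency
for the observed base to its background frequency, weighted by that
position's information content w_j = 2 + sum_b f_bj log2 f_bj (0 for a
fully ambiguous column, 2 for an invariant one), and the weighted sum is
normalized by sum_j w_j.  Higher MMS means a better match; a per-motif
hit threshold is the lowest score MAP-assigned to the highest-mean
component of a three-component Gaussian mixture fitted to an empirical
score pool.  Hits are then mapped to genes within a window of the gene
body and discretized into nested binary count features (>=1, >1, >2, >3
copies); continuous per-gene values (expression, ChIP hit counts) are
discretized at the 75th/90th/99th percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .loci import GeneAnnotation

__all__ = [
    "PWM",
    "MotifHit",
    "MixtureThreshold",
    "position_weights",
    "mms",
    "scan",
    "fit_threshold",
    "hits_to_gene_counts",
    "count_threshold_features",
    "percentile_features",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class PWM:
    """A position frequency matrix (rows A, C, G, T; columns sum to 1)."""

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be 4 x L")
        if self.matrix.shape[1] < 1:
            raise ValueError(f"{self.motif_id}: motif length must be >= 1")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            if (colsums <= 0).any():
                raise ValueError(f"{self.motif_id}: empty PWM column")
            self.matrix = self.matrix / colsums  # counts -> frequencies
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def smoothed(self) -> np.ndarray:
        """Pseudocounted, column-renormalized frequencies (never zero)."""
        f = self.matrix + self.pseudocount
        return f / f.sum(axis=0)

    @classmethod
    def from_counts(
        cls, motif_id: str, counts: np.ndarray, **kw
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(motif_id, counts / counts.sum(axis=0), **kw)


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    pos: int  # 0-based start on the forward strand
    strand: str
    mms: float


@dataclass
class MixtureThreshold:
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    threshold: float
    converged: bool
    log_likelihoods: np.ndarray = field(default_factory=lambda: np.array([]))


def position_weights(pwm: PWM, literal: bool = False) -> np.ndarray:
    """Information-content weight of each motif column, in [0, 2] bits.

    Default: w_j = 2 + sum_b f_bj log2 f_bj (Shannon information content of
    a 4-letter column).  ``literal=True`` selects the variant without the
    f_bj multiplier, w_j = 2 - sum_b log2 f_bj (pseudocounted), retained
    for comparison only.
    """
    f = pwm.smoothed if pwm.pseudocount > 0 else pwm.matrix
    if literal:
        return 2.0 - np.log2(np.where(f > 0, f, 1e-300)).sum(axis=0)
    plogp = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    return 2.0 + plogp.sum(axis=0)


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else -> -1 (windows containing it are skipped)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def mms(pwm: PWM, window: str, inverted_sign: bool = False) -> float:
    """Entropy-weighted motif match score of one L-length window.

    Positive for matches enriched over background; ``inverted_sign=True``
    negates the score (so strong matches are maximally negative).
    """
    if len(window) != pwm.length:
        raise ValueError("window length must equal motif length")
    w = position_weights(pwm)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError(f"{pwm.motif_id}: uninformative motif (sum of weights is 0)")
    f = pwm.smoothed if pwm.pseudocount > 0 else pwm.matrix
    lr = np.log2(np.where(f > 0, f, 1e-300) / pwm.background[:, None])
    codes = _encode(window)
    if (codes < 0).any():
        raise ValueError("window contains non-ACGT characters")
    score = float((w * lr[codes, np.arange(pwm.length)]).sum() / wsum)
    return -score if inverted_sign else score


def _scan_strand(
    pwm: PWM, codes: np.ndarray, lr: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """Scores of all windows of one encoded strand (NaN where non-ACGT)."""
    L = pwm.length
    n_win = codes.size - L + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    bad = np.zeros(n_win, dtype=bool)
    for j in range(L):
        cj = codes[j : j + n_win]
        bad |= cj < 0
        scores += w[j] * lr[np.where(cj < 0, 0, cj), j]
    scores /= w.sum()
    scores[bad] = np.nan
    return scores


def scan(
    pwm: PWM,
    sequence: str,
    threshold: float,
    seq_id: str = "",
    inverted_sign: bool = False,
) -> list[MotifHit]:
    """All motif hits with MMS >= threshold, on both strands.

    The reverse strand is scanned on the reverse complement; a hit there
    is reported at its forward-strand start coordinate.  Overlapping hits
    are all retained.  Windows containing non-ACGT characters are skipped.
    """
    if len(sequence) < pwm.length:
        return []
    w = position_weights(pwm)
    if w.sum() <= 0:
        raise ValueError(f"{pwm.motif_id}: uninformative motif (sum of weights is 0)")
    f = pwm.smoothed if pwm.pseudocount > 0 else pwm.matrix
    lr = np.log2(np.where(f > 0, f, 1e-300) / pwm.background[:, None])
    fwd = _encode(sequence)
    rc = _encode("".join(_COMPLEMENT.get(b, "N") for b in reversed(sequence.upper())))
    L, n = pwm.length, len(sequence)
    hits = []
    for strand, codes in (("+", fwd), ("-", rc)):
        scores = _scan_strand(pwm, codes, lr, w)
        if inverted_sign:
            scores = -scores
        ok = np.flatnonzero(~np.isnan(scores) & (
            scores <= threshold if inverted_sign else scores >= threshold
        ))
        for i in ok:
            pos = int(i) if strand == "+" else n - L - int(i)
            hits.append(MotifHit(seq_id, pos, strand, float(scores[i])))
    hits.sort(key=lambda h: (h.pos, h.strand))
    return hits


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [x[rng.integers(x.size)]]
    for _ in range(k - 1):
        d2 = np.min([(x - c) ** 2 for c in centers], axis=0)
        total = d2.sum()
        if total <= 0:
            centers.append(x[rng.integers(x.size)])
            continue
        centers.append(x[rng.choice(x.size, p=d2 / total)])
    return np.array(centers)


def _em_1d(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    mu = _kmeanspp_init(x, k, rng)
    var_floor = max(1e-10, 1e-6 * x.var())
    sd = np.full(k, max(x.std() / k, np.sqrt(var_floor)))
    w = np.full(k, 1.0 / k)
    lls = []
    converged = False
    for _ in range(max_iter):
        # E-step in log space
        logp = (
            np.log(w)[:, None]
            - 0.5 * np.log(2 * np.pi * sd[:, None] ** 2)
            - 0.5 * ((x[None, :] - mu[:, None]) / sd[:, None]) ** 2
        )
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum())
        resp = np.exp(logp - lse)
        # M-step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        mu = (resp * x).sum(axis=1) / nk
        var = (resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk
        sd = np.sqrt(np.maximum(var, var_floor))
        w = nk / x.size
        if lls and abs(ll - lls[-1]) < tol * (1 + abs(ll)):
            lls.append(ll)
            converged = True
            break
        lls.append(ll)
    return mu, sd, w, np.array(lls), converged


def fit_threshold(
    scores: Sequence[float],
    k: int = 3,
    rng: np.random.Generator | None = None,
    n_init: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureThreshold:
    """Hit threshold from a k-component 1-D Gaussian mixture (EM).

    k-means++ initialization, best of ``n_init`` restarts by final
    log-likelihood; components sorted by mean.  The threshold is the
    minimum score among points MAP-assigned to the highest-mean
    ("high confidence") component.  Requires >= 3k distinct values.
    """
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(scores, dtype=float)
    if np.unique(x).size < 3 * k:
        raise ValueError(f"need at least {3 * k} distinct score values")
    x = np.sort(x)  # order-invariant input
    best = None
    for _ in range(n_init):
        mu, sd, w, lls, conv = _em_1d(x, k, rng, tol, max_iter)
        if np.diff(lls).min(initial=0.0) < -1e-6 * (1 + abs(lls[-1])):
            raise AssertionError("EM log-likelihood decreased")
        if best is None or lls[-1] > best[3][-1]:
            best = (mu, sd, w, lls, conv)
    mu, sd, w, lls, conv = best
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    logp = (
        np.log(w)[:, None]
        - np.log(sd)[:, None]
        - 0.5 * ((x[None, :] - mu[:, None]) / sd[:, None]) ** 2
    )
    assign = logp.argmax(axis=0)
    top = x[assign == k - 1]
    if top.size:
        threshold = float(top.min())
    else:  # degenerate: no point MAP-assigned to the top component
        threshold = float(x[logp[k - 1].argmax()])
    return MixtureThreshold(
        means=mu, sds=sd, weights=w, threshold=threshold,
        converged=conv, log_likelihoods=lls,
    )


def hits_to_gene_counts(
    hits: Iterable[MotifHit],
    genes: Sequence[GeneAnnotation],
    window_bp: int,
) -> dict[str, int]:
    """Count hits whose start falls within window_bp of each gene body.

    A hit counts for every gene whose [tx_start, tx_end) expanded by
    ``window_bp`` contains the hit's start coordinate (strand-independent),
    so one hit can count for several genes.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    by_chrom: dict[str, list[int]] = {}
    for h in hits:
        by_chrom.setdefault(h.seq_id, []).append(h.pos)
    for positions in by_chrom.values():
        positions.sort()
    counts: dict[str, int] = {}
    for g in genes:
        positions = by_chrom.get(g.chrom, [])
        lo = np.searchsorted(positions, g.tx_start - window_bp, side="left")
        hi = np.searchsorted(positions, g.tx_end + window_bp, side="left")
        counts[g.gene_id] = int(hi - lo)
    return counts


def count_threshold_features(
    counts: Mapping[str, int], prefix: str = "tfbs"
) -> pd.DataFrame:
    """Nested binary features: >=1, >1, >2, >3 copies of a binding site."""
    genes = list(counts)
    c = np.array([counts[g] for g in genes], dtype=int)
    if (c < 0).any():
        raise ValueError("counts must be >= 0")
    data = {
        f"{prefix}_ge1": (c >= 1).astype(np.uint8),
        f"{prefix}_gt1": (c >= 2).astype(np.uint8),
        f"{prefix}_gt2": (c >= 3).astype(np.uint8),
        f"{prefix}_gt3": (c >= 4).astype(np.uint8),
    }
    return pd.DataFrame(data, index=genes)


def percentile_features(
    values: pd.DataFrame,
    percentiles: Sequence[float] = (75, 90, 99),
) -> pd.DataFrame:
    """Binary columns marking genes strictly above per-sample percentiles.

    For each (sample column, percentile) pair the cutoff is the linearly
    interpolated quantile of that column; membership is strict (a value
    exactly at the cutoff stays 0), so a constant column yields all zeros.
    """
    out = {}
    for col in values.columns:
        v = values[col].to_numpy(dtype=float)
        for p in percentiles:
            cutoff = np.percentile(v, p)
            out[f"{col}_p{p:g}"] = (v > cutoff).astype(np.uint8)
    return pd.DataFrame(out, index=values.index)
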