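"""Motif models, PWM scanning inside ChIP-seq peaks, and activity calls.

A binding motif is described by a position frequency matrix (PFM).  Scanning
uses a standard log-odds position weight matrix (PWM) with a
fraction-of-maximum-score threshold (a reproducible stand-in for a p-value
threshold).  A motif instance is *active* when it overlaps DNase I
hypersensitive sites (DHS) in every supplied cell type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .io_formats import GenomeSequence, GenomicInterval, encode_seq

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifModel:
    """A PFM for one binding motif: 4 x L count matrix (rows A,C,G,T)."""

    motif_id: str
    tf_name: str
    tf_family: str
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("PFM must be a 4 x L matrix")
        if counts.shape[1] < 4:
            raise ValueError("motif length must be >= 4")
        if np.any(counts < 0):
            raise ValueError("PFM counts must be non-negative")
        if np.any(counts.sum(axis=0) <= 0):
            raise ValueError("PFM has an all-zero column")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class PWM:
    """Log2-odds matrix derived from a PFM.

    ``log_odds[b, i] = log2(((counts[b,i] + pc*bg[b]) / (colsum_i + pc)) / bg[b])``
    """

    motif_id: str
    log_odds: np.ndarray
    background: np.ndarray
    pseudocount: float

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    def score(self, seq: str | np.ndarray) -> float:
        """Log-odds score (bits) of one L-mer; N anywhere gives -inf."""
        codes = encode_seq(seq) if isinstance(seq, str) else np.asarray(seq)
        if codes.size != self.length:
            raise ValueError("sequence length must equal motif length")
        if (codes >= 4).any():
            return float("-inf")
        return float(self.log_odds[codes, np.arange(self.length)].sum())


@dataclass
class BindingSite:
    """One motif match inside a peak; ``center = start + floor(L/2)``."""

    interval: GenomicInterval
    motif_id: str
    score: float
    active: bool = False

    @property
    def center(self) -> int:
        return self.interval.start + len(self.interval) // 2


def build_pwm(
    motif: MotifModel,
    pseudocount: float = 0.8,
    background: np.ndarray | None = None,
) -> PWM:
    """Standard log2-odds PWM with a background-split pseudocount."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or np.any(background <= 0) or not np.isclose(background.sum(), 1.0):
        raise ValueError("background must be 4 positive frequencies summing to 1")
    counts = motif.counts
    colsums = counts.sum(axis=0)
    freqs = (counts + pseudocount * background[:, None]) / (colsums + pseudocount)
    log_odds = np.log2(freqs / background[:, None])
    return PWM(motif.motif_id, log_odds, background, pseudocount)


def _scan_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Scores of every L-window of ``codes``; windows containing N get -inf."""
    L = log_odds.shape[1]
    lo5 = np.vstack([log_odds, np.full((1, L), -np.inf)])  # row 4 = N
    if codes.size < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lo5[windows, np.arange(L)].sum(axis=1)


def scan_motif(
    genome: GenomeSequence,
    peaks: list[GenomicInterval],
    pwm: PWM,
    threshold_fraction: float = 0.85,
) -> list[BindingSite]:
    """Scan both strands of every peak; report hits >= fraction of max score.

    Overlapping hits within one peak are resolved greedily by score
    (ties: leftmost start, then + strand); non-overlapping hits all kept.
    """
    if not (0 < threshold_fraction <= 1):
        raise ValueError("threshold_fraction must be in (0, 1]")
    L = pwm.length
    threshold = threshold_fraction * pwm.max_score
    # PWM for scoring the reverse-complement without flipping the sequence
    lo_rc = pwm.log_odds[::-1, ::-1]
    sites: list[BindingSite] = []
    n_short = 0
    for peak in peaks:
        codes = genome.codes(peak.chrom)[peak.start : peak.end]
        if codes.size < L:
            n_short += 1
            continue
        hits = []  # (score, start, strand)
        for strand, lo in (("+", pwm.log_odds), ("-", lo_rc)):
            scores = _scan_scores(codes, lo)
            for off in np.flatnonzero(scores >= threshold):
                hits.append((float(scores[off]), peak.start + int(off), strand))
        # best-first greedy resolution of overlaps
        hits.sort(key=lambda h: (-h[0], h[1], 0 if h[2] == "+" else 1))
        taken: list[tuple[int, int]] = []
        for score, start, strand in hits:
            if any(start < e and start + L > s for s, e in taken):
                continue
            taken.append((start, start + L))
            sites.append(
                BindingSite(
                    GenomicInterval(peak.chrom, start, start + L, strand,
                                    name=pwm.motif_id, score=round(score, 6)),
                    motif_id=pwm.motif_id,
                    score=score,
                )
            )
    if n_short:
        log.warning("skipped %d peaks shorter than the motif (%d bp)", n_short, L)
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return sites


def _build_trees(intervals: list[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def classify_activity(
    sites: list[BindingSite], dhs_sets: list[list[GenomicInterval]]
) -> list[BindingSite]:
    """Flag sites active iff they overlap (>=1 bp) every DHS set supplied."""
    if not dhs_sets:
        raise ValueError("at least one DHS set is required")
    tree_sets = [_build_trees(dhs) for dhs in dhs_sets]
    out = []
    for site in sites:
        iv = site.interval
        active = all(
            iv.chrom in trees and bool(trees[iv.chrom].overlap(iv.start, iv.end))
            for trees in tree_sets
        )
        out.append(BindingSite(iv, site.motif_id, site.score, active))
    return out


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [], []
    for s, e in zip(starts, ends):
        if merged_e and s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.array(merged_s), np.array(merged_e)


def _padded_merged(sites: list[BindingSite], pad: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in sites:
        c = s.center
        by_chrom.setdefault(s.interval.chrom, []).append((max(0, c - pad), c + pad + 1))
    return {
        chrom: _merge(np.array([p[0] for p in ivs]), np.array([p[1] for p in ivs]))
        for chrom, ivs in by_chrom.items()
    }


def _intersection_len(a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]) -> int:
    sa, ea = a
    sb, eb = b
    i = j = 0
    total = 0
    while i < len(sa) and j < len(sb):
        lo = max(sa[i], sb[j])
        hi = min(ea[i], eb[j])
        if hi > lo:
            total += hi - lo
        if ea[i] < eb[j]:
            i += 1
        else:
            j += 1
    return int(total)


def jaccard_overlap(
    sitesA: list[BindingSite], sitesB: list[BindingSite], pad: int = 50
) -> float:
    """bedtools-jaccard statistic on center +/- pad windows of two site sets."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if not sitesA or not sitesB:
        return 0.0
    A = _padded_merged(sitesA, pad)
    B = _padded_merged(sitesB, pad)
    inter = 0
    len_a = sum(int((e - s).sum()) for s, e in A.values())
    len_b = sum(int((e - s).sum()) for s, e in B.values())
    for chrom in set(A) & set(B):
        inter += _intersection_len(A[chrom], B[chrom])
    union = len_a + len_b - inter
    return inter / union if union else 0.0


def write_sites_bed(sites: list[BindingSite], path) -> None:
    """Catalog file: BED6 + motif_id, score, active columns."""
    with open(path, "w") as fh:
        fh.write("# uvtfbs site catalog; 0-based half-open; "
                 "cols: chrom,start,end,name,score,strand,motif_id,score_bits,active\n")
        for s in sites:
            iv = s.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.motif_id}\t0\t{iv.strand}"
                f"\t{s.motif_id}\t{s.score:.4f}\t{int(s.active)}\n"
            )


def read_sites_bed(path) -> list[BindingSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            iv = GenomicInterval(cols[0], int(cols[1]), int(cols[2]), cols[5], cols[3])
            sites.append(BindingSite(iv, cols[6], float(cols[7]), bool(int(cols[8]))))
    return sites
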