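"""UV-cohort filtering and k-mer background mutation model.

The cohort is reduced to UV-dominated samples (>= 70% C>T, counting G>A as
C>T on the opposite strand) and to C>T records.  A k-mer (k = 3 or 5)
substitution model assigns each pyrimidine-centered k-mer a mutability =
(cohort mutations at genome occurrences of that k-mer) / (genome occurrence
count), with every genomic position counted once under its pyrimidine-
centered representation.  Expected per-position mutation counts for a window
stack are the analytic expectation of redistributing each window's observed
mutations according to these mutabilities (a seeded Monte-Carlo mode
implements the same randomization explicitly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeSequence
from .window_stacking import WindowStack

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# k-mer coding

def _rc_code_table(k: int) -> np.ndarray:
    """Reverse-complement lookup for integer k-mer codes (base-4, A0 C1 G2 T3)."""
    codes = np.arange(4 ** k)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - tmp % 4)
        tmp //= 4
    return rc


def _center_base(codes: np.ndarray, k: int) -> np.ndarray:
    shift = 4 ** (k - 1 - k // 2)
    return (codes // shift) % 4


def kmer_codes(seq_codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer k-mer code centered at every position of an encoded sequence.

    Returns (codes, valid); positions whose context runs off the sequence or
    contains N are invalid (code 0, valid False).
    """
    n = seq_codes.shape[-1]
    half = k // 2
    out = np.zeros(seq_codes.shape, dtype=np.int64)
    valid = np.ones(seq_codes.shape, dtype=bool)
    for j in range(-half, half + 1):
        shifted = np.full(seq_codes.shape, 4, dtype=np.uint8)
        src = slice(max(0, -j), min(n, n - j))
        dst = slice(max(0, j), min(n, n + j))
        shifted[..., src] = seq_codes[..., dst]
        valid &= shifted < 4
        out = out * 4 + np.where(shifted < 4, shifted, 0)
    return out, valid


def decode_kmer(code: int, k: int) -> str:
    bases = []
    for _ in range(k):
        bases.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(bases))


def encode_kmer(kmer: str) -> int:
    code = 0
    for b in kmer:
        code = code * 4 + "ACGT".index(b)
    return code


# ---------------------------------------------------------------------------
# Cohort filter

def _is_ct(df: pd.DataFrame) -> pd.Series:
    return ((df["ref"] == "C") & (df["alt"] == "T")) | (
        (df["ref"] == "G") & (df["alt"] == "A")
    )


def filter_cohort(mutations: pd.DataFrame, ct_fraction_min: float = 0.70) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep samples whose C>T fraction (G>A counted as C>T) >= threshold.

    Within kept samples, only C>T/G>A records are retained.  Returns
    (filtered mutations, per-sample report).
    """
    df = mutations.copy()
    df["_ct"] = _is_ct(df)
    grp = df.groupby("sample", sort=True)["_ct"].agg(["size", "sum"])
    grp.columns = ["total_mutations", "n_ct"]
    grp["ct_fraction"] = np.where(
        grp["total_mutations"] > 0, grp["n_ct"] / grp["total_mutations"], 0.0
    )
    grp["kept"] = (grp["ct_fraction"] >= ct_fraction_min) & (grp["total_mutations"] > 0)
    grp["reason"] = np.where(
        grp["kept"], "",
        np.where(grp["total_mutations"] == 0, "empty", "ct_fraction"),
    )
    report = grp.reset_index()
    kept_samples = set(report.loc[report["kept"], "sample"])
    out = df[df["sample"].isin(kept_samples) & df["_ct"]].drop(columns="_ct")
    return out.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Substitution model

@dataclass
class SubstitutionModel:
    """Pyrimidine-centered k-mer -> mutability table.

    ``prob``, ``genome_counts`` and ``mutation_counts`` are indexed by
    canonical (pyrimidine-centered) integer k-mer codes; ``lookup`` maps ANY
    k-mer code to the mutability of its pyrimidine-centered representative,
    so purine-centered genomic positions score their opposite-strand context.
    """

    k: int
    prob: np.ndarray
    genome_counts: np.ndarray
    mutation_counts: np.ndarray
    lookup: np.ndarray

    def probability(self, kmer: str) -> float:
        return float(self.lookup[encode_kmer(kmer)])

    def to_frame(self) -> pd.DataFrame:
        k = self.k
        rows = []
        for code in np.flatnonzero(self.genome_counts + self.mutation_counts):
            rows.append(
                {
                    "kmer": decode_kmer(int(code), k),
                    "genome_count": int(self.genome_counts[code]),
                    "mutation_count": int(self.mutation_counts[code]),
                    "probability": float(self.prob[code]),
                }
            )
        return pd.DataFrame(rows, columns=["kmer", "genome_count", "mutation_count", "probability"])


def fit_substitution_model(
    mutations: pd.DataFrame, genome: GenomeSequence, k: int = 3
) -> SubstitutionModel:
    """Fit mutability = mutations / genome occurrences per pyrimidine k-mer."""
    if k not in (3, 5):
        raise ValueError("k must be 3 or 5")
    nk = 4 ** k
    rc = _rc_code_table(k)
    center = _center_base(np.arange(nk), k)
    is_pyr_center = (center == 1) | (center == 3)
    canon = np.where(is_pyr_center, np.arange(nk), rc)

    genome_counts = np.zeros(nk, dtype=np.int64)
    for chrom in genome:
        codes, valid = kmer_codes(genome.codes(chrom), k)
        genome_counts += np.bincount(canon[codes[valid]], minlength=nk)

    mutation_counts = np.zeros(nk, dtype=np.int64)
    for chrom, sub in mutations.groupby("chrom", sort=False):
        seq = genome.codes(chrom)
        codes, valid = kmer_codes(seq, k)
        pos = sub["pos"].to_numpy()
        ok = valid[pos]
        mutation_counts += np.bincount(canon[codes[pos[ok]]], minlength=nk)

    bad = (genome_counts == 0) & (mutation_counts > 0)
    if bad.any():
        kmers = [decode_kmer(int(c), k) for c in np.flatnonzero(bad)[:5]]
        raise ValueError(f"mutations observed at k-mers absent from the genome: {kmers}")
    with np.errstate(divide="ignore", invalid="ignore"):
        prob = np.where(genome_counts > 0, mutation_counts / np.maximum(genome_counts, 1), 0.0)
    lookup = prob[canon]
    return SubstitutionModel(k, prob, genome_counts, mutation_counts, lookup)


# ---------------------------------------------------------------------------
# Expected profiles

def _window_probs(stack: WindowStack, model: SubstitutionModel, rows: slice) -> np.ndarray:
    codes, valid = kmer_codes(stack.seqs[rows], model.k)
    p = model.lookup[codes]
    p[~valid] = 0.0
    return p


def expected_profile(
    stack: WindowStack,
    model: SubstitutionModel,
    chunk: int = 512,
    return_per_window: bool = False,
) -> np.ndarray:
    """Analytic per-position expected mutation counts for a stack.

    For window w with m_w observed mutations, the expected contribution to
    offset i is ``m_w * p_wi / sum_j p_wj`` — the expectation of placing the
    window's mutations multinomially by context mutability.  The total over
    offsets equals the observed total per window exactly.

    With ``return_per_window`` the (n_sites, window_length) matrix of
    per-window expectations is returned instead of the column sum.
    """
    wl = stack.config.window_length
    expected = np.zeros(wl)
    per_window = [] if return_per_window else None
    m = stack.window_mutations.astype(float)
    for lo in range(0, stack.n_sites, chunk):
        rows = slice(lo, min(lo + chunk, stack.n_sites))
        p = _window_probs(stack, model, rows)
        sums = p.sum(axis=1)
        mw = m[rows]
        zero = sums <= 0
        if np.any(zero & (mw > 0)):
            raise ValueError(
                f"{stack.motif_id}: window with observed mutations but all-zero "
                "context mutability"
            )
        sums[zero] = 1.0
        contrib = p * (mw / sums)[:, None]
        expected += contrib.sum(axis=0)
        if per_window is not None:
            per_window.append(contrib)
    stack.tracks["expected_mutations"] = expected
    if per_window is not None:
        return np.vstack(per_window) if per_window else np.empty((0, wl))
    return expected


def expected_profile_mc(
    stack: WindowStack,
    model: SubstitutionModel,
    n_reps: int = 10_000,
    seed: int = 0,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo expected profile: redistribute each window's mutations.

    Returns (mean per-position counts over replicates, per-position standard
    deviation across replicates).  Seeded and independent of the analytic
    path: mutations are placed by explicit multinomial sampling.
    """
    rng = np.random.default_rng(seed)
    wl = stack.config.window_length
    index_parts: list[np.ndarray] = []
    rep_base = (np.arange(n_reps, dtype=np.int64) * wl)[:, None]
    for lo in range(0, stack.n_sites, chunk):
        rows = slice(lo, min(lo + chunk, stack.n_sites))
        p = _window_probs(stack, model, rows)
        m = stack.window_mutations[rows]
        for wi in range(p.shape[0]):
            mw = int(m[wi])
            if mw == 0:
                continue
            pw = p[wi]
            total = pw.sum()
            if total <= 0:
                raise ValueError("window with mutations but zero mutability")
            cdf = np.cumsum(pw / total)
            offs = np.searchsorted(cdf, rng.random((n_reps, mw)))
            index_parts.append((rep_base + offs).ravel())
    if index_parts:
        flat = np.bincount(np.concatenate(index_parts), minlength=n_reps * wl)
    else:
        flat = np.zeros(n_reps * wl, dtype=np.int64)
    counts = flat.reshape(n_reps, wl)
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1)
    return mean, sd


def inactive_background_profile(
    inactive_stack: WindowStack, active_total_mutations: float
) -> np.ndarray:
    """Inactive-TFBS mutation profile scaled to the active stack's total.

    The observed per-position mutation counts of the inactive stack (same
    motif, same geometry) are rescaled so their sum matches the active
    stack's total observed mutations — an alternative expectation that keeps
    the inactive profile's shape.
    """
    if inactive_stack.n_sites == 0:
        raise ValueError("inactive stack is empty")
    track = inactive_stack.tracks.get("mutations")
    if track is None or track.sum() <= 0:
        raise ValueError("inactive stack has no mapped mutations")
    return track * (active_total_mutations / track.sum())
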