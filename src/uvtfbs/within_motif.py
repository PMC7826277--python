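"""Dipyrimidine-level analysis inside the binding motif.

For every motif-internal dipyrimidine conserved (same type, same offset,
same orientation-relative strand) in at least half of the motif's genomic
instances, the observed mutation/CPD count is compared with an expectation
built by sampling, from each window's own flanks, one dipyrimidine of the
same type embedded in the same tetranucleotide (5' base + dipyrimidine +
3' base).  Sampling is repeated (default 50 iterations) and averaged.

Coordinates here are *oriented*: offset = position relative to the motif
center after strand inversion; strand = relative to the motif orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .region_stats import poisson_g_test
from .window_stacking import WindowStack

log = logging.getLogger(__name__)

_DIPYR_NAMES = {(3, 3): "TT", (3, 1): "TC", (1, 3): "CT", (1, 1): "CC"}


def _rc4_table() -> np.ndarray:
    """Reverse-complement table for 4-mer codes (base-4 integers)."""
    codes = np.arange(256)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(4):
        rc = rc * 4 + (3 - tmp % 4)
        tmp //= 4
    return rc


_RC4 = _rc4_table()


@dataclass
class DipyrimidineSite:
    """One conserved dipyrimidine position within a motif."""

    motif_id: str
    offset: int          # oriented offset of the 5' base
    strand: str          # '+'/'-' relative to motif orientation
    dipyr: str           # TT / TC / CT / CC
    conservation: float
    observed: float = float("nan")
    expected: float = float("nan")
    percent_over_expected: float = float("nan")
    repair_pp_diff: float = float("nan")
    p_value: float = float("nan")
    n_skipped_windows: int = 0
    carriers: np.ndarray = field(default=None, repr=False)  # bool per window


def conserved_dipyrimidines(
    stack: WindowStack, min_conservation: float = 0.5
) -> list[DipyrimidineSite]:
    """Find motif dipyrimidines conserved in >= min_conservation of windows.

    Both orientation-relative strands are assessed (CPDs are strand
    specific); conservation requires one specific dipyrimidine type, not
    merely any pyrimidine pair.
    """
    cfg = stack.config
    hw = cfg.half_width
    motif_r = cfg.motif_width // 2
    n = stack.n_sites
    if n == 0:
        return []
    sites = []
    for j in range(-motif_r, motif_r):  # 5' base; pair (j, j+1) inside motif
        b1 = stack.seqs[:, hw + j].astype(np.int16)
        b2 = stack.seqs[:, hw + j + 1].astype(np.int16)
        for strand in "+-":
            if strand == "+":
                ok = ((b1 == 1) | (b1 == 3)) & ((b2 == 1) | (b2 == 3))
                t1, t2 = b1, b2
            else:
                ok = ((b1 == 0) | (b1 == 2)) & ((b2 == 0) | (b2 == 2))
                t1, t2 = 3 - b2, 3 - b1  # read 5'->3' on the minus strand
            if not ok.any():
                continue
            for (c1, c2), name in _DIPYR_NAMES.items():
                carriers = ok & (t1 == c1) & (t2 == c2)
                frac = carriers.sum() / n
                if frac >= min_conservation:
                    sites.append(
                        DipyrimidineSite(
                            stack.motif_id, j, strand, name, float(frac),
                            carriers=carriers,
                        )
                    )
    return sites


# ---------------------------------------------------------------------------
# Genomic coordinate mapping (oriented -> reference)

def site_genomic_coords(
    stack: WindowStack, oriented_index: np.ndarray, oriented_strand_minus: np.ndarray,
    window_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Map oriented (array index 0..2000, strand) to (leftmost genomic base
    of the pair, genomic strand is '-' flag).

    ``oriented_index`` is the array position of the pair's oriented 5' base.
    """
    starts = stack.starts[window_idx]
    inv = stack.minus[window_idx]
    wl = stack.config.window_length
    left = np.where(inv, starts + (wl - 1) - oriented_index - 1, starts + oriented_index)
    gminus = np.where(inv, ~oriented_strand_minus, oriented_strand_minus)
    return left.astype(np.int64), gminus


# ---------------------------------------------------------------------------
# Event lookup indices

class PositionIndex:
    """Count lookup by (chrom, strand, position) built from an event frame.

    CPD frames (chrom/pos5/strand/count) are stranded; mutation frames are
    strandless (strand key '.').
    """

    def __init__(self, events: pd.DataFrame):
        self._index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        self.total = 0.0
        if "pos5" in events.columns:
            self.stranded = True
            grouped = events.groupby(["chrom", "strand"], sort=False)
            for (chrom, strand), sub in grouped:
                agg = sub.groupby("pos5")["count"].sum()
                self._index[(chrom, strand)] = (
                    agg.index.to_numpy(np.int64), agg.to_numpy(float)
                )
            self.total = float(events["count"].sum())
        else:
            self.stranded = False
            for chrom, sub in events.groupby("chrom", sort=False):
                pos, cnt = np.unique(sub["pos"].to_numpy(np.int64), return_counts=True)
                self._index[(chrom, ".")] = (pos, cnt.astype(float))
            self.total = float(len(events))

    def counts_at(self, chrom: str, positions: np.ndarray, minus: np.ndarray | None = None) -> np.ndarray:
        out = np.zeros(positions.size)
        if self.stranded:
            assert minus is not None
            for strand, mask in (("+", ~minus), ("-", minus)):
                key = (chrom, strand)
                if key not in self._index or not mask.any():
                    continue
                pos_arr, cnt_arr = self._index[key]
                idx = np.searchsorted(pos_arr, positions[mask])
                idx_c = np.clip(idx, 0, pos_arr.size - 1)
                hit = (idx < pos_arr.size) & (pos_arr[idx_c] == positions[mask])
                vals = np.zeros(mask.sum())
                vals[hit] = cnt_arr[idx_c[hit]]
                out[mask] = vals
        else:
            key = (chrom, ".")
            if key in self._index:
                pos_arr, cnt_arr = self._index[key]
                idx = np.searchsorted(pos_arr, positions)
                idx_c = np.clip(idx, 0, pos_arr.size - 1)
                hit = (idx < pos_arr.size) & (pos_arr[idx_c] == positions)
                out[hit] = cnt_arr[idx_c[hit]]
        return out

    def pair_counts(self, stack: WindowStack, window_idx: np.ndarray,
                    oriented_index: np.ndarray, oriented_minus: np.ndarray) -> np.ndarray:
        """Events at a dipyrimidine pair: stranded lookup at the leftmost base
        for CPDs; both bases, strandless, for mutations."""
        left, gminus = site_genomic_coords(stack, oriented_index, oriented_minus, window_idx)
        chroms = np.asarray(stack.chroms, dtype=object)[window_idx]
        out = np.zeros(window_idx.size)
        for chrom in pd.unique(chroms):
            m = chroms == chrom
            if self.stranded:
                out[m] = self.counts_at(chrom, left[m], gminus[m])
            else:
                out[m] = self.counts_at(chrom, left[m]) + self.counts_at(chrom, left[m] + 1)
        return out


def observed_site_count(site: DipyrimidineSite, stack: WindowStack, index: PositionIndex) -> float:
    """Total events at the site over its carrier windows."""
    widx = np.flatnonzero(site.carriers)
    hw = stack.config.half_width
    oi = np.full(widx.size, hw + site.offset)
    om = np.full(widx.size, site.strand == "-")
    return float(index.pair_counts(stack, widx, oi, om).sum())


# ---------------------------------------------------------------------------
# Tetranucleotide-matched flank sampling

@dataclass
class SampledFlankPositions:
    """Drawn flank positions shared across tracks: one draw per carrier
    window per iteration (windows without a tetranucleotide match skipped)."""

    window_idx: np.ndarray       # (n_usable,)
    oriented_index: np.ndarray   # (n_iter, n_usable) array positions of 5' base
    oriented_minus: np.ndarray   # (n_iter, n_usable)
    n_skipped: int
    n_iter: int


def _tetra_codes(stack: WindowStack) -> tuple[np.ndarray, np.ndarray]:
    """Plus-strand tetranucleotide code centred on each pair's 5' base.

    Code at array position i covers bases (i-1, i, i+1, i+2); invalid (edge
    or N) positions get -1.
    """
    s = stack.seqs.astype(np.int16)
    n, wl = s.shape
    code = np.full((n, wl), -1, dtype=np.int16)
    b0, b1, b2, b3 = s[:, :-3], s[:, 1:-2], s[:, 2:-1], s[:, 3:]
    valid = (b0 < 4) & (b1 < 4) & (b2 < 4) & (b3 < 4)
    c = b0 * 64 + b1 * 16 + b2 * 4 + b3
    code[:, 1:-2] = np.where(valid, c, -1)
    return code, valid


def sample_matched_positions(
    site: DipyrimidineSite,
    stack: WindowStack,
    n_iter: int = 50,
    rng: np.random.Generator | None = None,
) -> SampledFlankPositions:
    """Draw, per iteration and per carrier window, one flank dipyrimidine of
    the same type in the same tetranucleotide context (either strand)."""
    rng = rng or np.random.default_rng()
    cfg = stack.config
    hw = cfg.half_width
    widx = np.flatnonzero(site.carriers)
    tetra, _ = _tetra_codes(stack)
    i_site = hw + site.offset
    t_site = tetra[widx, i_site].astype(np.int64)
    valid_site = t_site >= 0
    if site.strand == "-":
        t_site = np.where(valid_site, _RC4[np.clip(t_site, 0, 255)], -1)
    # flank array positions where the whole pair lies in the flanks
    flank = stack.regions.masks["flanks"]
    pair_in_flank = flank.copy()
    pair_in_flank[:-1] &= flank[1:]
    pair_in_flank[-1] = False
    fpos = np.flatnonzero(pair_in_flank)
    ft = tetra[widx][:, fpos]
    match_plus = ft == t_site[:, None]
    match_minus = ft == _RC4[np.clip(t_site, 0, 255)][:, None]
    match_minus &= t_site[:, None] >= 0
    match_plus &= t_site[:, None] >= 0
    m1 = match_plus.sum(axis=1)
    m2 = match_minus.sum(axis=1)
    mt = m1 + m2
    usable = mt > 0
    n_skipped = int((~usable).sum())
    if not usable.any():
        return SampledFlankPositions(
            np.empty(0, np.int64), np.empty((n_iter, 0), np.int64),
            np.empty((n_iter, 0), bool), n_skipped, n_iter,
        )
    rows_p, cols_p = np.nonzero(match_plus[usable])
    rows_m, cols_m = np.nonzero(match_minus[usable])
    rows = np.concatenate([rows_p, rows_m])
    order = np.argsort(rows, kind="stable")
    cand_pos = fpos[np.concatenate([cols_p, cols_m])[order]]
    cand_minus = np.concatenate(
        [np.zeros(rows_p.size, bool), np.ones(rows_m.size, bool)]
    )[order]
    rows_sorted = rows[order]
    nu = int(usable.sum())
    starts = np.searchsorted(rows_sorted, np.arange(nu))
    mt_u = mt[usable]
    draws = rng.integers(0, mt_u, size=(n_iter, nu))
    flat = starts[None, :] + draws
    return SampledFlankPositions(
        window_idx=widx[usable],
        oriented_index=cand_pos[flat],
        oriented_minus=cand_minus[flat],
        n_skipped=n_skipped,
        n_iter=n_iter,
    )


def sampled_track_sums(
    sampled: SampledFlankPositions, stack: WindowStack, index: PositionIndex
) -> np.ndarray:
    """Per-iteration total event counts at the drawn flank positions."""
    sums = np.zeros(sampled.n_iter)
    for it in range(sampled.n_iter):
        om = sampled.oriented_minus[it]
        sums[it] = index.pair_counts(
            stack, sampled.window_idx, sampled.oriented_index[it], om
        ).sum()
    return sums


def sample_matched_expectation(
    site: DipyrimidineSite,
    stack: WindowStack,
    index: PositionIndex,
    n_iter: int = 50,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[float, int]:
    """Expected event count at a site from tetranucleotide-matched flank
    sampling: mean of per-iteration sums.  Returns (expected, n_skipped);
    expected is NaN when no window has a matching flank tetranucleotide."""
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    sampled = sample_matched_positions(site, stack, n_iter, rng)
    if sampled.window_idx.size == 0:
        return float("nan"), sampled.n_skipped
    sums = sampled_track_sums(sampled, stack, index)
    return float(sums.mean()), sampled.n_skipped


def percent_over_expected(observed: float, expected: float) -> float:
    """100 * (observed - expected) / expected; NaN when expected <= 0."""
    if not np.isfinite(expected) or expected <= 0:
        return float("nan")
    return 100.0 * (observed - expected) / expected


def within_motif_repair(
    site: DipyrimidineSite,
    stack: WindowStack,
    cpd0_index: PositionIndex,
    cpd48_index: PositionIndex,
    genome_totals: tuple[float, float],
    sampled: SampledFlankPositions | None = None,
    n_iter: int = 50,
    rng: np.random.Generator | None = None,
) -> float:
    """Repair difference (percentage points) between a motif dipyrimidine
    and its matched flank expectation.

    Both timepoints are normalized by genome-wide CPD totals; repair is the
    percent change of the normalized count after 48 h; the result is
    (motif percent change) - (flank percent change).  NaN when the site has
    no 0h signal.
    """
    t0, t48 = genome_totals
    if t0 <= 0 or t48 <= 0:
        raise ValueError("genome totals must be positive")
    n0 = observed_site_count(site, stack, cpd0_index)
    n48 = observed_site_count(site, stack, cpd48_index)
    if n0 <= 0:
        return float("nan")
    if sampled is None:
        sampled = sample_matched_positions(site, stack, n_iter, rng or np.random.default_rng())
    if sampled.window_idx.size == 0:
        return float("nan")
    e0 = sampled_track_sums(sampled, stack, cpd0_index).mean()
    e48 = sampled_track_sums(sampled, stack, cpd48_index).mean()
    if e0 <= 0:
        return float("nan")
    pc_motif = 100.0 * (n48 / t48 - n0 / t0) / (n0 / t0)
    pc_flank = 100.0 * (e48 / t48 - e0 / t0) / (e0 / t0)
    return float(pc_motif - pc_flank)


def within_motif_table(
    stack: WindowStack,
    mutation_index: PositionIndex | None = None,
    cpd_indices: dict[str, PositionIndex] | None = None,
    genome_totals: dict[str, float] | None = None,
    n_iter: int = 50,
    min_conservation: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Full within-motif report: one row per (conserved site x track).

    Tracks analysed: 'mutations' (if a mutation index is given) and each CPD
    timepoint in ``cpd_indices``.  repair_pp_diff is attached to the rows of
    the 0h CPD track when both 0h and 48h indices plus genome totals are
    available.  The same drawn flank positions are reused across tracks
    within a site (one sampling per site per iteration).
    """
    rng = np.random.default_rng(seed)
    sites = conserved_dipyrimidines(stack, min_conservation)
    rows = []
    for site in sites:
        sampled = sample_matched_positions(site, stack, n_iter, rng)
        trackset: list[tuple[str, PositionIndex]] = []
        if mutation_index is not None:
            trackset.append(("mutations", mutation_index))
        for tp, idx in (cpd_indices or {}).items():
            trackset.append((tp, idx))
        pp = float("nan")
        if (cpd_indices and "cpd_0h" in cpd_indices and "cpd_48h" in cpd_indices
                and genome_totals):
            pp = within_motif_repair(
                site, stack, cpd_indices["cpd_0h"], cpd_indices["cpd_48h"],
                (genome_totals["cpd_0h"], genome_totals["cpd_48h"]),
                sampled=sampled,
            )
        for track, index in trackset:
            obs = observed_site_count(site, stack, index)
            if sampled.window_idx.size:
                exp = float(sampled_track_sums(sampled, stack, index).mean())
            else:
                exp = float("nan")
            stat, p = poisson_g_test(obs, exp) if np.isfinite(exp) else (float("nan"),) * 2
            rows.append(
                {
                    "motif_id": site.motif_id,
                    "offset": site.offset,
                    "strand": site.strand,
                    "type": site.dipyr,
                    "conservation": site.conservation,
                    "track": track,
                    "observed": obs,
                    "expected": exp,
                    "percent_over_expected": percent_over_expected(obs, exp),
                    "repair_pp_diff": pp if track == "cpd_0h" else float("nan"),
                    "p_value": p,
                    "n_skipped_windows": sampled.n_skipped,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)
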