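"""Oriented 2001-bp windows around motif centers, stacked per motif type.

Each active binding site contributes one window spanning 1000 nt on each side
of the motif center.  Windows on minus-strand motifs are inverted so that all
windows share the motif's reading orientation.  Events (mutations, CPDs at
each timepoint) are mapped to window offsets -1000..+1000 and summed column-
wise over the stack.

Four concentric regions partition each window: motif (21 bp), TFBS (101 bp,
containing the motif), DHS flanks (200 bp per side) and flanks (750 bp per
side).  Region summaries for "TFBS" include the motif positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeSequence
from .tfbs_catalog import BindingSite

log = logging.getLogger(__name__)

REGIONS = ("motif", "tfbs", "dhs_flanks", "flanks")


@dataclass(frozen=True)
class AnalysisConfig:
    """All numeric parameters of the analysis, with the study defaults."""

    half_width: int = 1000
    motif_width: int = 21
    tfbs_width: int = 101
    dhs_flank_width: int = 200   # per side
    flank_width: int = 750       # per side
    min_sites: int = 5000
    min_median_mutations: float = 2.0
    ct_fraction_min: float = 0.70
    conservation_min: float = 0.5
    sampling_iters: int = 50
    jaccard_pad: int = 50

    def __post_init__(self):
        wl = 2 * self.half_width + 1
        composed = self.tfbs_width + 2 * self.dhs_flank_width + 2 * self.flank_width
        if wl != composed:
            raise ValueError(
                f"inconsistent region widths: window {wl} != "
                f"tfbs {self.tfbs_width} + 2*{self.dhs_flank_width} + 2*{self.flank_width}"
            )
        if self.motif_width > self.tfbs_width:
            raise ValueError("motif must fit inside the TFBS")

    @property
    def window_length(self) -> int:
        return 2 * self.half_width + 1


@dataclass(frozen=True)
class RegionMask:
    """Per-offset region labels for one window geometry.

    ``partition`` assigns each offset exactly one label (motif positions are
    labelled 'motif'); ``masks`` holds per-region boolean masks where the
    'tfbs' mask *includes* the motif positions.
    """

    offsets: np.ndarray
    partition: np.ndarray
    masks: dict[str, np.ndarray]

    def counts(self) -> dict[str, int]:
        return {r: int(m.sum()) for r, m in self.masks.items()}


def region_mask(config: AnalysisConfig = AnalysisConfig()) -> RegionMask:
    """Label offsets -half_width..+half_width with the four analysis regions."""
    hw = config.half_width
    offsets = np.arange(-hw, hw + 1)
    a = np.abs(offsets)
    motif_r = config.motif_width // 2         # 10
    tfbs_r = config.tfbs_width // 2           # 50
    dhs_r = tfbs_r + config.dhs_flank_width   # 250
    masks = {
        "motif": a <= motif_r,
        "tfbs": a <= tfbs_r,                  # includes the motif
        "dhs_flanks": (a > tfbs_r) & (a <= dhs_r),
        "flanks": a > dhs_r,
    }
    partition = np.full(offsets.size, "flanks", dtype=object)
    partition[masks["dhs_flanks"]] = "dhs_flanks"
    partition[masks["tfbs"] & ~masks["motif"]] = "tfbs"
    partition[masks["motif"]] = "motif"
    return RegionMask(offsets, partition, masks)


class WindowStack:
    """All oriented windows of one motif type, with per-position tracks.

    Attributes
    ----------
    chroms, starts, minus : per-window chromosome, genomic start of offset
        -half_width, and orientation flag (True = motif on minus strand).
    seqs : (n_sites, window_length) uint8 array of *oriented* base codes
        (minus-strand windows are reverse-complemented).
    tracks : per-position event counts summed over windows, keyed by track
        name ('mutations', 'cpd_0h', ...).
    window_mutations : per-window mutation totals (filled by map_events).
    """

    def __init__(self, motif_id: str, config: AnalysisConfig = AnalysisConfig()):
        self.motif_id = motif_id
        self.config = config
        self.chroms: list[str] = []
        self.starts = np.empty(0, dtype=np.int64)
        self.minus = np.empty(0, dtype=bool)
        self.seqs = np.empty((0, config.window_length), dtype=np.uint8)
        self.tracks: dict[str, np.ndarray] = {}
        self.window_mutations = np.empty(0, dtype=np.int64)
        self.regions = region_mask(config)
        self.n_discarded = 0

    @property
    def n_sites(self) -> int:
        return self.seqs.shape[0]

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.config.half_width

    def copy_geometry(self) -> "WindowStack":
        new = WindowStack(self.motif_id, self.config)
        new.chroms = list(self.chroms)
        new.starts = self.starts.copy()
        new.minus = self.minus.copy()
        new.seqs = self.seqs.copy()
        return new


def extract_windows(
    sites: list[BindingSite],
    genome: GenomeSequence,
    config: AnalysisConfig = AnalysisConfig(),
    motif_id: str | None = None,
) -> WindowStack:
    """Build the oriented window stack for one motif's sites.

    Windows running past a chromosome end are discarded (counted, logged) so
    every column of the stack has equal depth.
    """
    if motif_id is None:
        motif_id = sites[0].motif_id if sites else "motif"
    stack = WindowStack(motif_id, config)
    hw = config.half_width
    wl = config.window_length
    chroms, starts, minus, seq_rows = [], [], [], []
    n_discarded = 0
    for site in sites:
        center = site.center
        chrom = site.interval.chrom
        start = center - hw
        if start < 0 or start + wl > genome.length(chrom):
            n_discarded += 1
            continue
        codes = genome.codes(chrom)[start : start + wl]
        if site.interval.strand == "-":
            codes = np.where(codes < 4, 3 - codes, 4).astype(np.uint8)[::-1]
            minus.append(True)
        else:
            minus.append(False)
        chroms.append(chrom)
        starts.append(start)
        seq_rows.append(codes)
    if n_discarded:
        log.info("%s: discarded %d windows crossing chromosome ends", motif_id, n_discarded)
    stack.chroms = chroms
    stack.starts = np.array(starts, dtype=np.int64)
    stack.minus = np.array(minus, dtype=bool)
    stack.seqs = (
        np.vstack(seq_rows) if seq_rows else np.empty((0, wl), dtype=np.uint8)
    )
    stack.window_mutations = np.zeros(stack.n_sites, dtype=np.int64)
    stack.n_discarded = n_discarded
    return stack


def _events_to_offsets(
    stack: WindowStack, chrom_arr: np.ndarray, pos_arr: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map genomic point events into (window_index, offset, weight) triples.

    An event falling inside several (overlapping) windows is mapped into each.
    """
    wl = stack.config.window_length
    hw = stack.config.half_width
    win_idx_parts, off_parts, w_parts = [], [], []
    chroms = np.asarray(stack.chroms, dtype=object)
    for chrom in pd.unique(chrom_arr):
        wmask = chroms == chrom
        if not wmask.any():
            continue
        widx = np.flatnonzero(wmask)
        wstarts = stack.starts[widx]
        order = np.argsort(wstarts, kind="stable")
        widx, wstarts = widx[order], wstarts[order]
        emask = chrom_arr == chrom
        pos = pos_arr[emask]
        w = weights[emask]
        # windows containing pos: start <= pos < start + wl
        lo = np.searchsorted(wstarts, pos - wl + 1, side="left")
        hi = np.searchsorted(wstarts, pos, side="right")
        n_hits = hi - lo
        keep = n_hits > 0
        if not keep.any():
            continue
        pos, w, lo, n_hits = pos[keep], w[keep], lo[keep], n_hits[keep]
        rep_pos = np.repeat(pos, n_hits)
        rep_w = np.repeat(w, n_hits)
        flat = np.concatenate([np.arange(l, l + n) for l, n in zip(lo, n_hits)])
        hit_widx = widx[flat]
        raw_off = rep_pos - (stack.starts[hit_widx] + hw)
        inv = stack.minus[hit_widx]
        offs = np.where(inv, -raw_off, raw_off)
        win_idx_parts.append(hit_widx)
        off_parts.append(offs)
        w_parts.append(rep_w)
    if not win_idx_parts:
        z = np.empty(0, dtype=np.int64)
        return z, z, z.astype(float)
    return (
        np.concatenate(win_idx_parts),
        np.concatenate(off_parts),
        np.concatenate(w_parts),
    )


def map_events(stack: WindowStack, events: pd.DataFrame, track: str | None = None) -> np.ndarray:
    """Map a mutation or CPD DataFrame onto the stack's per-position counts.

    Mutation frames (columns sample/chrom/pos/ref/alt) add 1 per record and
    update ``stack.window_mutations``; CPD frames (chrom/pos5/strand/count)
    add their counts, with the 5' (leftmost) base mapped as a point event.
    Returns the updated per-position track.
    """
    wl = stack.config.window_length
    hw = stack.config.half_width
    if "pos5" in events.columns:  # CPD map
        if track is None:
            track = f"cpd_{events.attrs.get('timepoint', 'cpd')}"
        chrom_arr = events["chrom"].to_numpy()
        pos_arr = events["pos5"].to_numpy()
        weights = events["count"].to_numpy().astype(np.int64)
        is_mut = False
    else:
        if track is None:
            track = "mutations"
        chrom_arr = events["chrom"].to_numpy()
        pos_arr = events["pos"].to_numpy()
        weights = np.ones(len(events), dtype=np.int64)
        is_mut = True
    widx, offs, w = _events_to_offsets(stack, chrom_arr, pos_arr, weights)
    counts = np.bincount(offs + hw, weights=w, minlength=wl)
    stack.tracks[track] = stack.tracks.get(track, np.zeros(wl)) + counts
    if is_mut:
        if stack.window_mutations.size != stack.n_sites:
            stack.window_mutations = np.zeros(stack.n_sites, dtype=np.int64)
        stack.window_mutations += np.bincount(widx, weights=w, minlength=stack.n_sites).astype(np.int64)
    return stack.tracks[track]


def filter_motifs(
    stacks: list[WindowStack],
) -> tuple[list[WindowStack], pd.DataFrame]:
    """Apply the motif-level inclusion filters.

    Keep a motif iff (i) it has at least ``min_sites`` stacked windows and
    (ii) the median of its 2001 per-position mutation counts is at least
    ``min_median_mutations``.  Returns (kept stacks, exclusion report).
    """
    kept = []
    rows = []
    for stack in stacks:
        cfg = stack.config
        muts = stack.tracks.get("mutations")
        if muts is None:
            raise ValueError(f"{stack.motif_id}: mutation track not mapped yet")
        med = float(np.median(muts))
        reasons = []
        if stack.n_sites < cfg.min_sites:
            reasons.append("site_count")
        if med < cfg.min_median_mutations:
            reasons.append("median_mutations")
        ok = not reasons
        rows.append(
            {
                "motif_id": stack.motif_id,
                "n_sites": stack.n_sites,
                "median_mutations": med,
                "kept": ok,
                "reason": ";".join(reasons) if reasons else "",
            }
        )
        if ok:
            kept.append(stack)
    return kept, pd.DataFrame(rows)


def normalize_window_track(stack: WindowStack, track: str) -> np.ndarray:
    """Per-position fractions of a track (sums to 1 over the window)."""
    if track not in stack.tracks:
        raise KeyError(f"track {track!r} not present")
    values = stack.tracks[track]
    total = values.sum()
    if total <= 0:
        raise ValueError(f"track {track!r} has zero total; cannot normalize")
    return values / total


STACK_COLUMNS = [
    "offset", "region", "n_windows", "mutation_count",
    "cpd_0h", "cpd_48h", "cpd_naked", "expected_mutations",
]


def stack_table(stack: WindowStack) -> pd.DataFrame:
    """The per-motif stack file: one row per offset."""
    wl = stack.config.window_length
    zero = np.zeros(wl)
    df = pd.DataFrame(
        {
            "offset": stack.regions.offsets,
            "region": stack.regions.partition,
            "n_windows": stack.n_sites,
            "mutation_count": stack.tracks.get("mutations", zero),
            "cpd_0h": stack.tracks.get("cpd_0h", zero),
            "cpd_48h": stack.tracks.get("cpd_48h", zero),
            "cpd_naked": stack.tracks.get("cpd_naked", zero),
            "expected_mutations": stack.tracks.get("expected_mutations", zero),
        }
    )
    return df


def write_stack(stack: WindowStack, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# uvtfbs stack for {stack.motif_id}; offsets are motif-oriented; "
            "0-based genomic coordinates upstream\n"
        )
        stack_table(stack).to_csv(fh, sep="\t", index=False)
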