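"""Relative repair inference from fixed-depth CPD maps, 48h prediction and
damage-mutation correlation.

CPD maps sequenced at a predetermined depth per timepoint carry only
*relative* information: comparing normalized 0h and 48h profiles reveals how
repair redistributes the surviving damage, never the absolute fraction of
lesions removed.  "Relative repair" at a position is the difference of its
normalized CPD fractions, rel0 - rel48 (window- or genome-normalized).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .region_stats import RegionSummary, g_test, chi2_gof
from .window_stacking import WindowStack, REGIONS

log = logging.getLogger(__name__)


@dataclass
class RepairProfile:
    """Per-position normalized damage at two timepoints and their difference."""

    motif_id: str
    rel0: np.ndarray
    rel48: np.ndarray
    repair: np.ndarray  # rel0 - rel48
    scope: str  # 'window' or 'genome'


def relative_repair_profile(
    cpd0: np.ndarray,
    cpd48: np.ndarray,
    scope: str = "window",
    genome_totals: tuple[float, float] | None = None,
    motif_id: str = "",
) -> RepairProfile:
    """Normalize both timepoint tracks and subtract, position by position.

    scope='window': divide each track by its window total (rel profiles sum
    to 1, so repair sums to 0 exactly).  scope='genome': divide by supplied
    genome-wide CPD totals per timepoint.
    """
    cpd0 = np.asarray(cpd0, dtype=float)
    cpd48 = np.asarray(cpd48, dtype=float)
    if cpd0.shape != cpd48.shape:
        raise ValueError("timepoint tracks must share the stack geometry")
    if scope == "window":
        t0, t48 = cpd0.sum(), cpd48.sum()
    elif scope == "genome":
        if genome_totals is None:
            raise ValueError("genome scope requires genome_totals=(T0, T48)")
        t0, t48 = genome_totals
    else:
        raise ValueError("scope must be 'window' or 'genome'")
    if t0 <= 0 or t48 <= 0:
        raise ValueError("zero CPD total at a timepoint")
    rel0 = cpd0 / t0
    rel48 = cpd48 / t48
    return RepairProfile(motif_id, rel0, rel48, rel0 - rel48, scope)


def percent_change_profile(profile: RepairProfile) -> np.ndarray:
    """Per-position percent change of normalized CPDs after 48 h.

    100 * (rel48 - rel0) / rel0; positions with rel0 = 0 are NaN.  Negative
    values = net repair; positive = apparent increase (retained, not
    clipped).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(
            profile.rel0 > 0, 100.0 * (profile.rel48 - profile.rel0) / profile.rel0, np.nan
        )


def damage_vs_naked_summary(
    stack: WindowStack,
    observed_track: str = "cpd_0h",
    naked_track: str = "cpd_naked",
    test: str = "chi2_gof",
) -> list[RegionSummary]:
    """Observed 0h CPDs vs naked-DNA expectation, per region.

    Both tracks are window-normalized; the log2 ratio compares region sums of
    fractions; the p-value is a goodness of fit across the region's positions
    with the expectation given by the naked fractions scaled to the observed
    regional total.
    """
    observed = stack.tracks[observed_track]
    naked = stack.tracks[naked_track]
    if observed.sum() <= 0 or naked.sum() <= 0:
        raise ValueError("zero total in observed or naked track")
    obs_frac = observed / observed.sum()
    naked_frac = naked / naked.sum()
    testfun = chi2_gof if test == "chi2_gof" else g_test
    out = []
    for region in REGIONS:
        mask = stack.regions.masks[region]
        o, e = float(obs_frac[mask].sum()), float(naked_frac[mask].sum())
        if e <= 0:
            out.append(RegionSummary(stack.motif_id, region, "cpd0_vs_naked",
                                     o, e, float("nan"), float("nan"), float("nan"), test))
            continue
        ratio = float(np.log2(o / e)) if o > 0 else float("nan")
        stat, p = testfun(observed[mask], naked[mask])
        out.append(RegionSummary(stack.motif_id, region, "cpd0_vs_naked",
                                 o, e, ratio, stat, p, test))
    return out


def region_repair_ratio(
    profile: RepairProfile,
    regions,
    reference: str = "flanks",
    counts0: np.ndarray | None = None,
    counts48: np.ndarray | None = None,
) -> list[RegionSummary]:
    """log2 of mean per-position repair in each region over the reference.

    Means (not sums) make regions of different widths comparable.  Regions
    with non-positive mean repair are reported missing (log undefined).
    When raw count tracks are supplied, a 2-cell G-test (region vs reference
    48h counts against 0h-proportional expectation) provides the p-value for
    differential repair.
    """
    ref_mask = regions.masks[reference]
    ref_mean = float(profile.repair[ref_mask].mean())
    if ref_mean <= 0:
        raise ValueError(f"reference region {reference!r} has non-positive mean repair")
    metric = f"repair_vs_{reference}"
    out = []
    for region in REGIONS:
        mask = regions.masks[region]
        mean = float(profile.repair[mask].mean())
        ratio = float(np.log2(mean / ref_mean)) if mean > 0 else float("nan")
        stat = p = float("nan")
        if counts0 is not None and counts48 is not None and region != reference:
            o = np.array([counts48[mask].sum(), counts48[ref_mask].sum()])
            e = np.array([counts0[mask].sum(), counts0[ref_mask].sum()])
            stat, p = g_test(o, e)
        out.append(
            RegionSummary(profile.motif_id, region, metric, mean, ref_mean,
                          ratio, stat, p, "g_test")
        )
    return out


def predict_cpds_48h(
    target0: np.ndarray,
    ref0: np.ndarray,
    ref48: np.ndarray,
    pseudocount: float = 0.5,
    smooth_window: int = 5,
) -> np.ndarray:
    """Predict a 48h profile for an independent 0h map.

    The per-position transformation learned from the reference dataset,
    ``f_i = rel(ref48)_i / rel(ref0)_i``, is applied to the normalized target
    0h profile and the result renormalized to sum 1.  Add-half pseudocounts
    on the reference tracks and a moving-average smoothing of f tame
    zero-count positions (pass pseudocount=0, smooth_window=1 to disable).
    The prediction is invariant to rescaling any input track.
    """
    target0 = np.asarray(target0, dtype=float)
    ref0 = np.asarray(ref0, dtype=float)
    ref48 = np.asarray(ref48, dtype=float)
    if not (target0.shape == ref0.shape == ref48.shape):
        raise ValueError("all tracks must share the stack geometry")
    if target0.sum() <= 0 or ref0.sum() <= 0 or ref48.sum() <= 0:
        raise ValueError("zero-total track")
    # pseudocount is applied on mean-1 rescaled tracks: equivalent to adding
    # `pseudocount` counts when the mean per-position count is 1, and exactly
    # scale-invariant for any input rescaling
    r0 = ref0 / ref0.mean() + pseudocount
    r48 = ref48 / ref48.mean() + pseudocount
    rel_r0 = r0 / r0.sum()
    rel_r48 = r48 / r48.sum()
    f = rel_r48 / rel_r0
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        fp = np.pad(f, pad, mode="edge")
        f = np.convolve(fp, kernel, mode="valid")[: f.size]
    rel_t0 = target0 / target0.sum()
    pred = rel_t0 * f
    total = pred.sum()
    if total <= 0:
        raise ValueError("no overlap between target and reference support")
    return pred / total


@dataclass
class DamageMutationCorrelation:
    r: float
    p_value: float
    n: int
    motif_ids: list[str]
    x: np.ndarray  # log2 TFBS/flanks mutation ratio
    y: np.ndarray  # log2 TFBS/flanks CPD ratio


def correlate_damage_mutation(
    stacks: list[WindowStack],
    cpd_track: str = "cpd_0h",
    mutation_track: str = "mutations",
    cpd_tracks: dict[str, np.ndarray] | None = None,
) -> DamageMutationCorrelation:
    """Pearson r across motifs of TFBS-vs-flanks ratios: mutations vs CPDs.

    For each motif, x = log2(mean per-position mutation count in the TFBS /
    mean in the flanks) and y = the same ratio for the chosen CPD track
    (per-motif arrays may be supplied via ``cpd_tracks`` keyed by motif_id,
    e.g. for predicted 48h profiles).  Motifs with zero flank signal are
    excluded with a warning.
    """
    xs, ys, ids = [], [], []
    for stack in stacks:
        mask_t = stack.regions.masks["tfbs"]
        mask_f = stack.regions.masks["flanks"]
        mut = stack.tracks[mutation_track]
        if cpd_tracks is not None:
            cpd = cpd_tracks[stack.motif_id]
        else:
            cpd = stack.tracks[cpd_track]
        m_t, m_f = mut[mask_t].mean(), mut[mask_f].mean()
        c_t, c_f = cpd[mask_t].mean(), cpd[mask_f].mean()
        if min(m_t, m_f, c_t, c_f) <= 0:
            log.warning("%s excluded from correlation (zero region signal)", stack.motif_id)
            continue
        xs.append(np.log2(m_t / m_f))
        ys.append(np.log2(c_t / c_f))
        ids.append(stack.motif_id)
    if len(xs) < 3:
        raise ValueError("need >= 3 motifs with usable signal for a correlation")
    x = np.array(xs)
    y = np.array(ys)
    r, p = stats.pearsonr(x, y)
    return DamageMutationCorrelation(float(r), float(p), len(xs), ids, x, y)
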