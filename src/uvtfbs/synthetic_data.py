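"""Self-contained synthetic study generator with recorded ground truth.

Emulates the statistical structure of the real inputs: a genome with
implanted motif instances inside ChIP-seq-like peaks, DHS marks over the
active subset, fixed-depth single-nucleotide CPD maps (naked / 0h / 48h)
and a melanoma-like mutation cohort dominated by C>T at dipyrimidines.

Design notes
------------
* CPD maps at every timepoint are multinomial draws of the SAME total read
  depth, so only relative damage information survives — as in fixed-depth
  Damage-seq.  Planted survival fractions are therefore expressed RELATIVE
  to the genomic background (background survival = 1.0).
* One TF's windows cover ~0.4% of a real genome (6000 x 2001 bp / 3 Gbp).
  Rather than materialising gigabases, the background damage mass
  (``background_mass_ratio`` x the active-window mass, default 249 = a 0.4%
  window share) is carried by a compact dedicated chromosome (``chrBg``)
  of real sequence; positions are genuine dipyrimidines and totals exact.
* Mutations are placed at cytosines of dipyrimidine cells with probability
  proportional to the damage SURVIVING at 48 h (switchable to 0h damage for
  negative controls), times nothing else — the context dependence of the
  cohort then emerges from the dipyrimidine requirement itself.
* Every output is a deterministic function of (params, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GenomeSequence,
    GenomicInterval,
    write_bed,
    write_cpd_map,
    write_fasta,
    write_jaspar_pfm,
    write_mutations,
)
from .tfbs_catalog import MotifModel, build_pwm
from .window_stacking import AnalysisConfig

log = logging.getLogger(__name__)

CHROM = "chr1"
BG_CHROM = "chrBg"

#: per-dipyrimidine-type baseline CPD formation rates (TT lesions dominate)
DEFAULT_BASELINE = {"TT": 1.0, "TC": 0.35, "CT": 0.25, "CC": 0.10}

#: 48h survival fraction per window region, relative to background (=1.0)
DEFAULT_SURVIVAL = {"motif": 0.8, "tfbs": 0.7, "dhs_flanks": 0.5, "flanks": 0.4}


@dataclass(frozen=True)
class StudyParams:
    """The synthetic study conditions (generator defaults = study design)."""

    genome_length: int | None = None     # auto: fits all sites with margins
    background_length: int = 2_000_000
    gc_fraction: float = 0.5
    motif_length: int = 21
    motif_sharpness: float = 0.97
    motif_consensus: str | None = None   # fixed consensus (else random per seed)
    n_active: int = 6000
    n_inactive: int = 600
    min_spacing: int = 2101              # > window length: windows disjoint
    window_read_depth: float = 10_000.0  # expected 0h reads per active window
    background_mass_ratio: float = 249.0 # background : active-window 0h mass
    baseline_damage: tuple = tuple(sorted(DEFAULT_BASELINE.items()))
    survival: tuple = tuple(sorted(DEFAULT_SURVIVAL.items()))
    background_survival: float = 1.0
    motif_damage_multiplier: float = 1.0
    damage_spike: tuple | None = None    # (oriented 5' offset, strand, factor)
    n_samples: int = 136
    muts_per_sample: int = 30_000
    ct_fraction: float = 0.90
    mutation_source: str = "48h"         # '48h' (repair shapes mutations) or '0h'

    @property
    def baseline(self) -> dict[str, float]:
        return dict(self.baseline_damage)

    @property
    def survival_by_region(self) -> dict[str, float]:
        return dict(self.survival)

    def resolved_genome_length(self) -> int:
        if self.genome_length is not None:
            return self.genome_length
        n = self.n_active + self.n_inactive
        return n * self.min_spacing + 2 * 1200


@dataclass
class SyntheticTruth:
    """Planted parameters plus derived quantities needed by oracles."""

    seed: int
    params: StudyParams
    consensus: str
    motif: MotifModel
    sites: pd.DataFrame            # center, strand, active
    n_reads_per_timepoint: int = 0
    global_mean_survival: float = float("nan")  # intensity-weighted
    expected_repair_pp_diff: float = float("nan")

    def to_json(self) -> str:
        d = {
            "seed": self.seed,
            "params": dataclasses.asdict(self.params),
            "consensus": self.consensus,
            "n_sites": int(len(self.sites)),
            "n_active": int(self.sites["active"].sum()),
            "n_reads_per_timepoint": int(self.n_reads_per_timepoint),
            "global_mean_survival": self.global_mean_survival,
            "expected_repair_pp_diff": self.expected_repair_pp_diff,
        }
        return json.dumps(d, indent=2, default=str)


# ---------------------------------------------------------------------------
# Genome and sites

def generate_genome(length: int, gc_fraction: float, seed: int) -> GenomeSequence:
    """I.i.d. genome of one chromosome at the stated GC content."""
    if length < 10 * 2001:
        raise ValueError("genome must be at least 10 window lengths long")
    if not (0 <= gc_fraction <= 1):
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return GenomeSequence({CHROM: codes})


def make_motif(length: int = 21, seed: int = 0, sharpness: float = 0.97,
               motif_id: str = "SYN0001.1", tf_name: str = "SYNTF",
               consensus: str | None = None) -> MotifModel:
    """Sharp PFM whose consensus carries dipyrimidines on both strands.

    The consensus is random per seed unless supplied explicitly.
    """
    from .io_formats import encode_seq

    rng = np.random.default_rng(seed)
    if consensus is not None:
        if len(consensus) != length:
            raise ValueError("consensus length must equal motif length")
        consensus = encode_seq(consensus).astype(np.int64)
    else:
        for _ in range(1000):
            consensus = rng.integers(0, 4, size=length)
            pyr = (consensus == 1) | (consensus == 3)
            pur = ~pyr
            pairs_plus = int((pyr[:-1] & pyr[1:]).sum())
            pairs_minus = int((pur[:-1] & pur[1:]).sum())
            if pairs_plus >= 2 and pairs_minus >= 1:
                break
    counts = np.full((4, length), (1 - sharpness) / 3 * 1000.0)
    counts[consensus, np.arange(length)] = sharpness * 1000.0
    return MotifModel(motif_id, tf_name, "Synthetic", counts)


def implant_sites(
    genome: GenomeSequence,
    motif: MotifModel,
    n_active: int,
    n_inactive: int = 0,
    min_spacing: int = 2101,
    seed: int = 0,
    min_score_fraction: float = 0.9,
) -> tuple[GenomeSequence, pd.DataFrame, list, list[list[GenomicInterval]]]:
    """Write motif instances into the genome on a regular grid.

    Instances are sampled from the PFM's column frequencies with rejection
    until they score at least ``min_score_fraction`` of the PWM maximum
    (bound sites are high-affinity matches).  Active sites get DHS cover in
    both synthetic cell types; all sites get a peak.

    Returns (genome', sites table, peaks, [dhs_set1, dhs_set2]).
    """
    rng = np.random.default_rng(seed)
    L = motif.length
    wl = 2001
    n = n_active + n_inactive
    margin = 1200
    codes = genome.codes(CHROM).copy()
    if margin * 2 + (n - 1) * min_spacing + wl // 2 >= codes.size:
        raise ValueError("genome too short for the requested sites; increase length")
    if min_spacing < wl:
        log.warning("min_spacing < window length: windows will overlap")
    centers = margin + np.arange(n) * min_spacing
    active = np.zeros(n, dtype=bool)
    active[rng.permutation(n)[:n_active]] = True
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    pwm = build_pwm(motif)
    probs = motif.counts / motif.counts.sum(axis=0, keepdims=True)
    cum = np.cumsum(probs, axis=0)
    threshold = min_score_fraction * pwm.max_score
    consensus_codes = motif.counts.argmax(axis=0)

    half = L // 2
    for i in range(n):
        inst = None
        for _ in range(100):
            u = rng.random(L)
            cand = (u[None, :] <= cum).argmax(axis=0)
            if pwm.log_odds[cand, np.arange(L)].sum() >= threshold:
                inst = cand
                break
        if inst is None:
            inst = consensus_codes
        if strands[i] == "-":
            inst = (3 - inst)[::-1]
        start = centers[i] - half
        codes[start : start + L] = inst.astype(np.uint8)

    genome2 = GenomeSequence({CHROM: codes})
    sites = pd.DataFrame({"center": centers, "strand": strands, "active": active})
    peaks = [GenomicInterval(CHROM, int(c) - 80, int(c) + 81, ".", "peak") for c in centers]
    dhs1 = [GenomicInterval(CHROM, int(c) - 150, int(c) + 151) for c in centers[active]]
    dhs2 = [GenomicInterval(CHROM, int(c) - 140, int(c) + 141) for c in centers[active]]
    return genome2, sites, peaks, [dhs1, dhs2]


# ---------------------------------------------------------------------------
# Damage law

_TYPE_ORDER = ("TT", "TC", "CT", "CC")
_PAIR_TO_TYPE = {(3, 3): 0, (3, 1): 1, (1, 3): 2, (1, 1): 3}


@dataclass
class CellTable:
    """All dipyrimidine cells of one chromosome with planted intensities.

    ``pos`` = leftmost genomic base of the pair; ``minus`` = lesion on the
    minus strand (reference shows a purine pair); ``type_idx`` indexes
    TT/TC/CT/CC read 5'->3' on the lesion strand.
    """

    chrom: str
    pos: np.ndarray
    minus: np.ndarray
    type_idx: np.ndarray
    naked: np.ndarray = None
    i0: np.ndarray = None
    i48: np.ndarray = None


def _vectorized_types(codes: np.ndarray, positions: np.ndarray, minus: np.ndarray) -> np.ndarray:
    """Fast type computation used in _find_cells replacement."""
    b1 = codes[positions].astype(np.int16)
    b2 = codes[positions + 1].astype(np.int16)
    a = np.where(minus, 3 - b2, b1)
    b = np.where(minus, 3 - b1, b2)
    # map (a,b) in {T,C}^2 to index: TT0 TC1 CT2 CC3
    return ((a == 1) * 2 + (b == 1)).astype(np.int8)


def find_dipyrimidine_cells(codes: np.ndarray, chrom: str) -> CellTable:
    b1, b2 = codes[:-1], codes[1:]
    pyr = lambda x: (x == 1) | (x == 3)  # noqa: E731
    pur = lambda x: (x == 0) | (x == 2)  # noqa: E731
    plus_pos = np.flatnonzero(pyr(b1) & pyr(b2))
    minus_pos = np.flatnonzero(pur(b1) & pur(b2))
    pos = np.concatenate([plus_pos, minus_pos])
    minus = np.concatenate([np.zeros(plus_pos.size, bool), np.ones(minus_pos.size, bool)])
    t = _vectorized_types(codes, pos, minus)
    order = np.argsort(pos, kind="stable")
    return CellTable(chrom, pos[order], minus[order], t[order])


def _survival_profile(config: AnalysisConfig, survival: dict[str, float]) -> np.ndarray:
    """Survival by |offset| within a window (regions are symmetric)."""
    from .window_stacking import region_mask

    mask = region_mask(config)
    prof = np.empty(config.window_length)
    for region in ("motif", "tfbs", "dhs_flanks", "flanks"):
        m = mask.masks[region] if region not in ("tfbs",) else (
            mask.masks["tfbs"] & ~mask.masks["motif"]
        )
        prof[m] = survival[region]
    return prof


@dataclass
class DamageLaw:
    """Per-cell planted intensities for both chromosomes plus bookkeeping."""

    cells_main: CellTable
    cells_bg: CellTable
    window_mask: np.ndarray       # per cells_main cell: inside an active window
    n_reads: int
    global_mean_survival: float


def build_damage_law(
    genome: GenomeSequence,
    truth: SyntheticTruth,
    config: AnalysisConfig = AnalysisConfig(),
) -> DamageLaw:
    """Assign planted 0h/48h/naked intensities to every dipyrimidine cell."""
    p = truth.params
    baseline = np.array([p.baseline[t] for t in _TYPE_ORDER])
    codes = genome.codes(CHROM)
    cells = find_dipyrimidine_cells(codes, CHROM)

    hw = config.half_width
    wl = config.window_length
    surv_prof = _survival_profile(config, p.survival_by_region)

    surv_pos = np.full(codes.size, p.background_survival)
    mult_pos = np.ones(codes.size)
    window_pos = np.zeros(codes.size, dtype=bool)
    active_sites = truth.sites[truth.sites["active"]]
    motif_r = config.motif_width // 2
    for c in active_sites["center"].to_numpy():
        surv_pos[c - hw : c + hw + 1] = surv_prof
        window_pos[c - hw : c + hw + 1] = True
        if p.motif_damage_multiplier != 1.0:
            mult_pos[c - motif_r : c + motif_r + 1] = p.motif_damage_multiplier

    cells.naked = baseline[cells.type_idx]
    cells.i0 = cells.naked * mult_pos[cells.pos]
    if p.damage_spike is not None:
        off, strand, factor = p.damage_spike
        spike_idx = _spike_cell_indices(cells, active_sites, int(off), strand, config)
        cells.i0[spike_idx] *= float(factor)
    cells.i48 = cells.i0 * surv_pos[cells.pos]
    window_mask = window_pos[cells.pos]

    # background chromosome carries background_mass_ratio x active-window mass
    if BG_CHROM in genome:
        bg = find_dipyrimidine_cells(genome.codes(BG_CHROM), BG_CHROM)
    else:
        bg = CellTable(BG_CHROM, np.empty(0, np.int64), np.empty(0, bool),
                       np.empty(0, np.int8))
    bg.naked = baseline[bg.type_idx]
    win_mass = cells.i0[window_mask].sum()
    if bg.pos.size and p.background_mass_ratio > 0:
        bg_scale = p.background_mass_ratio * win_mass / bg.naked.sum()
        bg.naked = bg.naked * bg_scale
    else:
        bg.naked = bg.naked * 0.0
    bg.i0 = bg.naked.copy()
    bg.i48 = bg.i0 * p.background_survival

    total0 = cells.i0.sum() + bg.i0.sum()
    total48 = cells.i48.sum() + bg.i48.sum()
    n_reads = int(round(p.window_read_depth * len(active_sites) * total0 / win_mass))
    return DamageLaw(cells, bg, window_mask, n_reads, float(total48 / total0))


def _spike_cell_indices(
    cells: CellTable, active_sites: pd.DataFrame, offset: int, strand: str,
    config: AnalysisConfig,
) -> np.ndarray:
    """Indices of cells at one oriented motif dipyrimidine across sites."""
    hw = config.half_width
    centers = active_sites["center"].to_numpy()
    site_minus = active_sites["strand"].to_numpy() == "-"
    want_minus = strand == "-"
    # oriented pair (offset, offset+1) -> genomic leftmost base
    left = np.where(site_minus, centers - offset - 1, centers + offset)
    gminus = np.where(site_minus, not want_minus, want_minus)
    key = left * 2 + gminus
    cell_key = cells.pos * 2 + cells.minus
    order = np.argsort(cell_key)
    idx = np.searchsorted(cell_key[order], key)
    idx_c = np.clip(idx, 0, cell_key.size - 1)
    hit = cell_key[order][idx_c] == key
    return order[idx_c[hit]]


def simulate_cpd_maps(
    genome: GenomeSequence,
    truth: SyntheticTruth,
    depth_per_window: float | None = None,
    seed: int = 0,
    config: AnalysisConfig = AnalysisConfig(),
    law: DamageLaw | None = None,
) -> tuple[dict[str, pd.DataFrame], DamageLaw]:
    """Fixed-depth multinomial CPD maps at naked / 0h / 48h.

    Every timepoint samples the SAME total read count (absolute repair
    information is deliberately destroyed; only redistribution survives).
    """
    p = truth.params
    if law is None:
        law = build_damage_law(genome, truth, config)
    if depth_per_window is not None and depth_per_window != p.window_read_depth:
        scale = depth_per_window / p.window_read_depth
        n_reads = int(round(law.n_reads * scale))
    else:
        n_reads = law.n_reads
    rng = np.random.default_rng(seed)
    maps = {}
    for name, attr in (("cpd_naked", "naked"), ("cpd_0h", "i0"), ("cpd_48h", "i48")):
        intensity = np.concatenate(
            [getattr(law.cells_main, attr), getattr(law.cells_bg, attr)]
        )
        draws = rng.multinomial(n_reads, intensity / intensity.sum())
        nz = np.flatnonzero(draws)
        n_main = law.cells_main.pos.size
        pos = np.concatenate([law.cells_main.pos, law.cells_bg.pos])
        minus = np.concatenate([law.cells_main.minus, law.cells_bg.minus])
        df = pd.DataFrame(
            {
                "chrom": np.where(nz < n_main, CHROM, BG_CHROM),
                "pos5": pos[nz],
                "strand": np.where(minus[nz], "-", "+"),
                "count": draws[nz].astype(np.int64),
            }
        )
        tp = {"cpd_naked": "naked", "cpd_0h": "0h", "cpd_48h": "48h"}[name]
        df.attrs["timepoint"] = tp
        maps[name] = df
    truth.n_reads_per_timepoint = n_reads
    truth.global_mean_survival = law.global_mean_survival
    surv = p.survival_by_region
    truth.expected_repair_pp_diff = float(
        100.0 * (surv["motif"] - surv["flanks"]) / law.global_mean_survival
    )
    return maps, law


# ---------------------------------------------------------------------------
# Mutation cohort

def simulate_mutation_cohort(
    genome: GenomeSequence,
    truth: SyntheticTruth,
    law: DamageLaw,
    n_samples: int | None = None,
    muts_per_sample: int | None = None,
    ct_fraction: float | np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """C>T mutations placed at cytosines proportional to surviving damage.

    The UV component of each sample is drawn from dipyrimidine cells that
    contain a cytosine on the lesion strand, weighted by the 48h-surviving
    (or, if configured, 0h) damage intensity; lesions on the minus strand
    are recorded as G>A.  The remaining (1 - ct_fraction) of records are
    uniform non-C>T noise.
    """
    p = truth.params
    n_samples = n_samples if n_samples is not None else p.n_samples
    muts_per_sample = muts_per_sample if muts_per_sample is not None else p.muts_per_sample
    if ct_fraction is None:
        ct_fraction = p.ct_fraction
    ct_arr = np.broadcast_to(np.asarray(ct_fraction, dtype=float), (n_samples,))
    rng = np.random.default_rng(seed)

    attr = "i48" if p.mutation_source == "48h" else "i0"
    weights = []
    cpos, cminus = [], []
    chrom_flags = []
    for cells, is_bg in ((law.cells_main, False), (law.cells_bg, True)):
        has_c = cells.type_idx > 0  # TC, CT, CC contain a C on the lesion strand
        w = getattr(cells, attr)[has_c]
        weights.append(w)
        t = cells.type_idx[has_c]
        pos = cells.pos[has_c]
        minus = cells.minus[has_c]
        # genomic position of the (a) C within the pair on the lesion strand
        # type TC: C is the 3' base; CT: 5' base; CC: random base
        three_prime = (t == 1) | ((t == 3) & (rng.random(t.size) < 0.5))
        # oriented 3' base = genomic right base on '+', left base on '-'
        offset = np.where(three_prime != minus, 1, 0)
        cpos.append(pos + offset)
        cminus.append(minus)
        chrom_flags.append(np.full(pos.size, is_bg))
    w = np.concatenate(weights)
    cpos = np.concatenate(cpos)
    cminus = np.concatenate(cminus)
    is_bg = np.concatenate(chrom_flags)
    if w.sum() <= 0:
        raise ValueError("no eligible cytosine-containing dipyrimidine cells")
    cdf = np.cumsum(w / w.sum())

    rows_sample, rows_chrom, rows_pos, rows_ref, rows_alt = [], [], [], [], []
    main_codes = genome.codes(CHROM)
    bg_codes = genome.codes(BG_CHROM) if BG_CHROM in genome else None
    for si in range(n_samples):
        sample = f"S{si:03d}"
        n_ct = int(round(muts_per_sample * ct_arr[si]))
        n_other = muts_per_sample - n_ct
        if n_ct:
            picks = np.searchsorted(cdf, rng.random(n_ct))
            rows_sample.append(np.full(n_ct, sample, dtype=object))
            rows_chrom.append(np.where(is_bg[picks], BG_CHROM, CHROM))
            rows_pos.append(cpos[picks])
            rows_ref.append(np.where(cminus[picks], "G", "C"))
            rows_alt.append(np.where(cminus[picks], "A", "T"))
        if n_other:
            gpos = rng.integers(0, main_codes.size, size=n_other)
            refs = main_codes[gpos]
            # non-C>T noise: pick alts that never read as C>T on either strand
            alt_choices = {0: "CG", 1: "AG", 2: "CT", 3: "AG", 4: "AG"}
            alts = np.array(
                [alt_choices[int(r)][rng.integers(0, 2)] for r in refs], dtype=object
            )
            ok = refs < 4
            rows_sample.append(np.full(int(ok.sum()), sample, dtype=object))
            rows_chrom.append(np.full(int(ok.sum()), CHROM, dtype=object))
            rows_pos.append(gpos[ok])
            rows_ref.append(np.array(["ACGT"[int(r)] for r in refs[ok]], dtype=object))
            rows_alt.append(alts[ok])
    df = pd.DataFrame(
        {
            "sample": np.concatenate(rows_sample),
            "chrom": np.concatenate(rows_chrom),
            "pos": np.concatenate(rows_pos).astype(np.int64),
            "ref": np.concatenate(rows_ref),
            "alt": np.concatenate(rows_alt),
        }
    )
    return df


# ---------------------------------------------------------------------------
# Full study

@dataclass
class StudyData:
    genome: GenomeSequence
    motif: MotifModel
    truth: SyntheticTruth
    peaks: list
    dhs_sets: list
    maps: dict[str, pd.DataFrame]
    mutations: pd.DataFrame
    law: DamageLaw


def generate_study(params: StudyParams = StudyParams(), seed: int = 0,
                   config: AnalysisConfig = AnalysisConfig()) -> StudyData:
    """Generate a complete synthetic study from (params, seed)."""
    ss = np.random.SeedSequence([seed, 20260926]).spawn(6)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    length = params.resolved_genome_length()
    genome = generate_genome(length, params.gc_fraction, sub[0])
    bg_rng = np.random.default_rng(sub[1])
    p_bg = np.array([(1 - params.gc_fraction) / 2, params.gc_fraction / 2,
                     params.gc_fraction / 2, (1 - params.gc_fraction) / 2])
    bg_codes = bg_rng.choice(4, size=params.background_length, p=p_bg).astype(np.uint8)
    motif = make_motif(params.motif_length, sub[2], params.motif_sharpness,
                       consensus=params.motif_consensus)
    genome1, sites, peaks, dhs_sets = implant_sites(
        genome, motif, params.n_active, params.n_inactive, params.min_spacing, sub[3]
    )
    genome_full = GenomeSequence({CHROM: genome1.codes(CHROM), BG_CHROM: bg_codes})
    truth = SyntheticTruth(seed, params, motif.consensus, motif, sites)
    maps, law = simulate_cpd_maps(genome_full, truth, seed=sub[4], config=config)
    mutations = simulate_mutation_cohort(genome_full, truth, law, seed=sub[5])
    return StudyData(genome_full, motif, truth, peaks, dhs_sets, maps, mutations, law)


def write_study(study: StudyData, outdir: str | Path) -> None:
    """Emit the study as plain-text files plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(study.genome, outdir / "genome.fa")
    write_bed(study.peaks, outdir / "peaks.bed")
    write_bed(study.dhs_sets[0], outdir / "dhs1.bed")
    write_bed(study.dhs_sets[1], outdir / "dhs2.bed")
    write_jaspar_pfm(study.motif, outdir / "motif.pfm")
    study.truth.sites.to_csv(outdir / "sites_truth.tsv", sep="\t", index=False)
    write_mutations(study.mutations, outdir / "mutations.tsv")
    for name, df in study.maps.items():
        write_cpd_map(df, outdir / f"{name}.bed")
    (outdir / "truth.json").write_text(study.truth.to_json())
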