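"""End-to-end orchestration: catalog -> stack -> expect -> repair ->
within-motif -> report, with a reproducibility manifest.

Every stage is a pure function of (inputs, config, seed); running twice with
the same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import damage_repair, mutation_expectation, region_stats, tfbs_catalog
from .io_formats import GenomeSequence
from .synthetic_data import StudyData, StudyParams, generate_study
from .window_stacking import (
    AnalysisConfig,
    WindowStack,
    extract_windows,
    filter_motifs,
    map_events,
    write_stack,
)
from .within_motif import PositionIndex, within_motif_table

log = logging.getLogger(__name__)


@dataclass
class MotifAnalysis:
    """All per-motif results for one window stack."""

    stack: WindowStack
    region_summaries: pd.DataFrame
    repair_window: damage_repair.RepairProfile | None = None
    repair_genome: damage_repair.RepairProfile | None = None
    within_motif: pd.DataFrame | None = None


@dataclass
class PipelineResult:
    catalog_sites: list
    n_active: int
    cohort_report: pd.DataFrame
    filter_report: pd.DataFrame
    analyses: list[MotifAnalysis]
    manifest: dict


def build_catalog(
    genome: GenomeSequence,
    peaks,
    motif,
    dhs_sets,
    threshold_fraction: float = 0.85,
    pseudocount: float = 0.8,
):
    """Scan the motif over peaks and classify activity by DHS overlap."""
    pwm = tfbs_catalog.build_pwm(motif, pseudocount=pseudocount)
    sites = tfbs_catalog.scan_motif(genome, peaks, pwm, threshold_fraction)
    return tfbs_catalog.classify_activity(sites, dhs_sets)


def stack_motif(
    genome: GenomeSequence,
    sites,
    mutations: pd.DataFrame,
    cpd_maps: dict[str, pd.DataFrame],
    config: AnalysisConfig = AnalysisConfig(),
    motif_id: str | None = None,
) -> WindowStack:
    """Extract active-site windows and map all event tracks."""
    active = [s for s in sites if s.active]
    stack = extract_windows(active, genome, config, motif_id=motif_id)
    map_events(stack, mutations)
    for name, df in cpd_maps.items():
        map_events(stack, df, track=name)
    return stack


def analyze_motif(
    stack: WindowStack,
    genome: GenomeSequence,
    mutations: pd.DataFrame,
    cpd_maps: dict[str, pd.DataFrame],
    model: mutation_expectation.SubstitutionModel,
    seed: int = 0,
    config: AnalysisConfig = AnalysisConfig(),
) -> MotifAnalysis:
    """Expected profile, region summaries, repair profiles and the
    within-motif dipyrimidine table for one stack."""
    mutation_expectation.expected_profile(stack, model)
    summaries = region_stats.summarize_regions(
        stack, "mutations", "expected_mutations", "mutations", test="g_test"
    )
    genome_totals = {name: float(df["count"].sum()) for name, df in cpd_maps.items()}
    repair_window = repair_genome = None
    if "cpd_0h" in stack.tracks and "cpd_48h" in stack.tracks:
        repair_window = damage_repair.relative_repair_profile(
            stack.tracks["cpd_0h"], stack.tracks["cpd_48h"], "window",
            motif_id=stack.motif_id,
        )
        repair_genome = damage_repair.relative_repair_profile(
            stack.tracks["cpd_0h"], stack.tracks["cpd_48h"], "genome",
            genome_totals=(genome_totals["cpd_0h"], genome_totals["cpd_48h"]),
            motif_id=stack.motif_id,
        )
        summaries += damage_repair.region_repair_ratio(
            repair_genome, stack.regions, "flanks",
            counts0=stack.tracks["cpd_0h"], counts48=stack.tracks["cpd_48h"],
        )
    if "cpd_0h" in stack.tracks and "cpd_naked" in stack.tracks:
        summaries += damage_repair.damage_vs_naked_summary(stack)
    mut_index = PositionIndex(mutations)
    cpd_indices = {name: PositionIndex(df) for name, df in cpd_maps.items()}
    wm = within_motif_table(
        stack,
        mutation_index=mut_index,
        cpd_indices=cpd_indices,
        genome_totals=genome_totals,
        n_iter=config.sampling_iters,
        min_conservation=config.conservation_min,
        seed=seed,
    )
    return MotifAnalysis(
        stack, region_stats.summaries_frame(summaries), repair_window,
        repair_genome, wm,
    )


def run_all(
    params: StudyParams = StudyParams(),
    seed: int = 0,
    outdir: str | Path | None = None,
    config: AnalysisConfig = AnalysisConfig(),
    threshold_fraction: float = 0.85,
    study: StudyData | None = None,
) -> PipelineResult:
    """Run the whole pipeline on a (generated or supplied) synthetic study.

    Writes, when ``outdir`` is given: sites.bed, cohort_report.tsv,
    filter_report.tsv, substitution_model.tsv, stack_<motif>.tsv,
    region_summaries.tsv, repair_profile_<motif>.tsv, within_motif.tsv and
    manifest.json.
    """
    if study is None:
        study = generate_study(params, seed, config)
    genome = study.genome
    sites = build_catalog(
        genome, study.peaks, study.motif, study.dhs_sets, threshold_fraction
    )
    n_active = sum(s.active for s in sites)
    filtered, cohort_report = mutation_expectation.filter_cohort(
        study.mutations, config.ct_fraction_min
    )
    stack = stack_motif(genome, sites, filtered, study.maps, config,
                        motif_id=study.motif.motif_id)
    kept, filter_report = filter_motifs([stack])
    model = mutation_expectation.fit_substitution_model(filtered, genome, k=3)
    analyses = []
    for st in kept:
        analyses.append(
            analyze_motif(st, genome, filtered, study.maps, model, seed, config)
        )

    manifest = {
        "seed": seed,
        "config": dataclasses.asdict(config),
        "params": dataclasses.asdict(params),
        "threshold_fraction": threshold_fraction,
        "n_catalog_sites": len(sites),
        "n_active_sites": int(n_active),
        "n_windows": int(stack.n_sites),
        "n_windows_discarded": int(stack.n_discarded),
        "cohort_kept": int(cohort_report["kept"].sum()),
        "cohort_total": int(len(cohort_report)),
        "motifs_kept": int(filter_report["kept"].sum()),
    }
    result = PipelineResult(sites, int(n_active), cohort_report, filter_report,
                            analyses, manifest)
    if outdir is not None:
        write_outputs(result, model, Path(outdir))
    return result


def _md5(path: Path) -> str:
    h = hashlib.md5()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(result: PipelineResult, model, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tfbs_catalog.write_sites_bed(result.catalog_sites, outdir / "sites.bed")
    with open(outdir / "cohort_report.tsv", "w") as fh:
        fh.write("# per-sample C>T fractions; kept iff fraction >= threshold\n")
        result.cohort_report.to_csv(fh, sep="\t", index=False)
    with open(outdir / "filter_report.tsv", "w") as fh:
        fh.write("# motif inclusion filters: site count and median mutations\n")
        result.filter_report.to_csv(fh, sep="\t", index=False)
    with open(outdir / "substitution_model.tsv", "w") as fh:
        fh.write("# pyrimidine-centered k-mer mutabilities\n")
        model.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")
    all_summaries = []
    all_within = []
    for an in result.analyses:
        write_stack(an.stack, outdir / f"stack_{an.stack.motif_id}.tsv")
        all_summaries.append(an.region_summaries)
        if an.within_motif is not None:
            all_within.append(an.within_motif)
        if an.repair_window is not None:
            prof = pd.DataFrame(
                {
                    "offset": an.stack.regions.offsets,
                    "rel0": an.repair_window.rel0,
                    "rel48": an.repair_window.rel48,
                    "repair": an.repair_window.repair,
                }
            )
            with open(outdir / f"repair_profile_{an.stack.motif_id}.tsv", "w") as fh:
                fh.write("# window-normalized relative repair (rel0 - rel48)\n")
                prof.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    if all_summaries:
        with open(outdir / "region_summaries.tsv", "w") as fh:
            fh.write("# region-level observed/expected summaries; "
                     "G-test for deviation calls, chi2 for timepoint homogeneity\n")
            pd.concat(all_summaries).to_csv(fh, sep="\t", index=False,
                                            float_format="%.10g")
    if all_within:
        with open(outdir / "within_motif.tsv", "w") as fh:
            fh.write("# conserved motif dipyrimidines vs tetranucleotide-matched "
                     "flank expectation\n")
            pd.concat(all_within).to_csv(fh, sep="\t", index=False,
                                         float_format="%.10g")
    manifest = dict(result.manifest)
    manifest["output_checksums"] = {
        p.name: _md5(p) for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.bed"))
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
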