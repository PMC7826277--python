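"""Shared fixtures: tiny deterministic genomes and a small synthetic study."""

import numpy as np
import pytest

from uvtfbs.io_formats import GenomeSequence, GenomicInterval
from uvtfbs.synthetic_data import StudyParams, generate_study
from uvtfbs.tfbs_catalog import BindingSite
from uvtfbs.window_stacking import AnalysisConfig, extract_windows, map_events


SMALL_PARAMS = StudyParams(
    n_active=300,
    n_inactive=30,
    background_length=200_000,
    window_read_depth=2_000.0,
    background_mass_ratio=20.0,
    n_samples=20,
    muts_per_sample=20_000,
)


@pytest.fixture(scope="session")
def small_study():
    """A 300-site synthetic study shared (read-only) across tests."""
    return generate_study(SMALL_PARAMS, seed=7)


def stack_from_truth(study, config=AnalysisConfig(), active_only=True, map_all=True):
    """Build a window stack directly from the planted site table."""
    sites = []
    table = study.truth.sites
    if active_only:
        table = table[table["active"]]
    L = study.motif.length
    half = L // 2
    for center, strand in zip(table["center"], table["strand"]):
        iv = GenomicInterval("chr1", int(center) - half, int(center) - half + L, strand)
        sites.append(BindingSite(iv, study.motif.motif_id, 0.0, True))
    stack = extract_windows(sites, study.genome, config, motif_id=study.motif.motif_id)
    if map_all:
        from uvtfbs.mutation_expectation import filter_cohort

        filtered, _ = filter_cohort(study.mutations)
        map_events(stack, filtered)
        for name, df in study.maps.items():
            map_events(stack, df, track=name)
    return stack


@pytest.fixture(scope="session")
def small_stack(small_study):
    return stack_from_truth(small_study)


@pytest.fixture()
def tiny_genome():
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
    return GenomeSequence({"chr1": seq})
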