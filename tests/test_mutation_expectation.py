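"""Cohort filter, k-mer substitution model and expected mutation profiles."""

import numpy as np
import pandas as pd
import pytest

from uvtfbs.io_formats import GenomeSequence, GenomicInterval, encode_seq, revcomp_codes
from uvtfbs.mutation_expectation import (
    encode_kmer,
    expected_profile,
    expected_profile_mc,
    filter_cohort,
    fit_substitution_model,
    inactive_background_profile,
    kmer_codes,
)
from uvtfbs.tfbs_catalog import BindingSite
from uvtfbs.window_stacking import AnalysisConfig, WindowStack, extract_windows, map_events


def _muts(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt"])


class TestFilterCohort:
    def _cohort(self, n_ct, n_other, sample="s1"):
        rows = [(sample, "chr1", i, "C", "T") for i in range(n_ct)]
        rows += [(sample, "chr1", 1000 + i, "A", "G") for i in range(n_other)]
        return _muts(rows)

    def test_exactly_70_percent_kept(self):
        filtered, report = filter_cohort(self._cohort(70, 30))
        assert report.loc[0, "kept"]
        assert len(filtered) == 70  # non-C>T records dropped

    def test_69_percent_dropped_entirely(self):
        filtered, report = filter_cohort(self._cohort(69, 31))
        assert not report.loc[0, "kept"]
        assert len(filtered) == 0

    def test_g_to_a_counts_as_ct_and_is_retained(self):
        df = _muts([("s1", "chr1", 1, "G", "A"), ("s1", "chr1", 2, "C", "T")])
        filtered, report = filter_cohort(df)
        assert report.loc[0, "ct_fraction"] == 1.0
        assert len(filtered) == 2
        assert set(filtered["ref"]) == {"C", "G"}


class TestFitModel:
    def test_hand_enumerated_tcg(self):
        # genome TCGTCGTCG: three TCG occurrences (centers at 1, 4, 7);
        # two mutations at the first two centers -> prob[TCG] = 2/3
        genome = GenomeSequence({"chr1": "TCGTCGTCG"})
        muts = _muts([("s1", "chr1", 1, "C", "T"), ("s1", "chr1", 4, "C", "T")])
        model = fit_substitution_model(muts, genome, k=3)
        assert model.probability("TCG") == pytest.approx(2 / 3)

    def test_no_mutations_all_zero(self):
        genome = GenomeSequence({"chr1": "ACGTACGTAC"})
        model = fit_substitution_model(_muts([]).astype({"pos": int}), genome, k=3)
        assert model.prob.sum() == 0

    def test_purine_center_scores_opposite_strand_context(self):
        # G>A at a G is a C>T on the minus strand: lookup at the purine-
        # centered code must equal the pyrimidine-centered probability
        genome = GenomeSequence({"chr1": "TCGTCGTCG"})
        muts = _muts([("s1", "chr1", 1, "C", "T")])
        model = fit_substitution_model(muts, genome, k=3)
        assert model.lookup[encode_kmer("CGA")] == model.probability("TCG")

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(4)
        codes = rng.integers(0, 4, 3000).astype(np.uint8)
        genome_f = GenomeSequence({"chr1": codes})
        genome_r = GenomeSequence({"chr1": revcomp_codes(codes)})
        pyr = np.flatnonzero((codes == 1) | (codes == 3))[:100]
        muts_f = _muts([
            ("s", "chr1", int(p), "CT"[int(codes[p] == 3)], "TC"[int(codes[p] == 3)])
            for p in pyr
        ])
        n = codes.size
        muts_r = _muts([
            ("s", "chr1", int(n - 1 - p), "GA"[int(codes[p] == 3)], "AG"[int(codes[p] == 3)])
            for p in pyr
        ])
        mf = fit_substitution_model(muts_f, genome_f, k=3)
        mr = fit_substitution_model(muts_r, genome_r, k=3)
        assert np.array_equal(mf.genome_counts, mr.genome_counts)
        assert np.allclose(mf.prob, mr.prob)

    def test_recovers_planted_rate_table(self):
        """Mutations drawn from a known per-kmer rate table are recovered
        proportionally (parameter recovery within binomial error)."""
        rng = np.random.default_rng(11)
        codes = rng.integers(0, 4, 200_000).astype(np.uint8)
        genome = GenomeSequence({"chr1": codes})
        kc, valid = kmer_codes(codes, 3)
        # plant: TCG mutates at 3x the rate of ACA
        rates = {encode_kmer("TCG"): 0.3, encode_kmer("ACA"): 0.1}
        rows = []
        for code, rate in rates.items():
            pos = np.flatnonzero(valid & (kc == code))
            hit = pos[rng.random(pos.size) < rate]
            for p in hit:
                ref = "ACGT"[codes[p]]
                rows.append(("s", "chr1", int(p), ref, "T" if ref == "C" else "A"))
        model = fit_substitution_model(_muts(rows), genome, k=3)
        ratio = model.probability("TCG") / model.probability("ACA")
        assert ratio == pytest.approx(3.0, rel=0.2)


def _toy_stack(n_windows=40, seed=5, genome_len=200_000):
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, genome_len).astype(np.uint8)
    genome = GenomeSequence({"chr1": codes})
    sites = []
    for i in range(n_windows):
        c = 1100 + i * 2101
        strand = "+" if rng.random() < 0.5 else "-"
        sites.append(
            BindingSite(GenomicInterval("chr1", c - 10, c + 11, strand), "M", 1.0, True)
        )
    stack = extract_windows(sites, genome, AnalysisConfig())
    # scatter mutations at pyrimidine positions inside the windows
    rows = []
    for i in range(stack.n_sites):
        start = stack.starts[i]
        window = codes[start:start + 2001]
        pyr = np.flatnonzero((window == 1) | (window == 3))
        for p in rng.choice(pyr, size=6, replace=False):
            ref = "ACGT"[window[p]]
            rows.append(("s", "chr1", int(start + p), ref, "T" if ref == "C" else "C"))
    muts = _muts(rows)
    map_events(stack, muts)
    return genome, stack, muts


class TestExpectedProfile:
    def test_uniform_mutability_gives_uniform_expectation(self):
        genome, stack, muts = _toy_stack(n_windows=4)
        from uvtfbs.mutation_expectation import SubstitutionModel

        nk = 4 ** 3
        model = SubstitutionModel(
            3, np.ones(nk), np.ones(nk, dtype=np.int64),
            np.ones(nk, dtype=np.int64), np.ones(nk),
        )
        exp = expected_profile(stack, model)
        total = stack.window_mutations.sum()
        # every offset with full context carries ~ total / 2001
        interior = exp[1:-1]
        assert np.allclose(interior, total / 1999, rtol=1e-9)

    def test_per_window_conservation_is_exact(self):
        genome, stack, muts = _toy_stack()
        model = fit_substitution_model(
            muts[(muts.ref == "C") & (muts.alt == "T")], genome, 3
        )
        exp = expected_profile(stack, model)
        assert exp.sum() == pytest.approx(stack.window_mutations.sum(), abs=1e-9)

    def test_monte_carlo_matches_analytic(self):
        genome, stack, muts = _toy_stack(n_windows=20)
        model = fit_substitution_model(
            muts[(muts.ref == "C") & (muts.alt == "T")], genome, 3
        )
        exp = expected_profile(stack, model)
        mc_mean, mc_sd = expected_profile_mc(stack, model, n_reps=2000, seed=1)
        sem = mc_sd / np.sqrt(2000)
        z = np.abs(mc_mean - exp) / np.where(sem > 0, sem, 1.0)
        # Sidak-style familywise 3-sigma bound across 2001 offsets
        assert z.max() < 4.5

    def test_mutability_only_at_center_concentrates_expectation(self):
        """Windows of all-A with a unique TCG at the center: a model whose
        only mutable k-mer is TCG must put the entire expectation at offset 0."""
        from uvtfbs.mutation_expectation import SubstitutionModel, encode_kmer

        cfg = AnalysisConfig()
        stack = WindowStack("M", cfg)
        n = 5
        seqs = np.zeros((n, cfg.window_length), dtype=np.uint8)  # all A
        seqs[:, 999:1002] = encode_seq("TCG")
        stack.seqs = seqs
        stack.starts = np.zeros(n, dtype=np.int64)
        stack.minus = np.zeros(n, dtype=bool)
        stack.chroms = ["chr1"] * n
        stack.window_mutations = np.full(n, 4, dtype=np.int64)
        nk = 4 ** 3
        lookup = np.zeros(nk)
        lookup[encode_kmer("TCG")] = 1.0
        model = SubstitutionModel(3, lookup, np.ones(nk, np.int64),
                                  np.ones(nk, np.int64), lookup)
        exp = expected_profile(stack, model)
        assert exp[1000] == pytest.approx(n * 4)
        assert exp.sum() == pytest.approx(n * 4)


class TestInactiveBackground:
    def test_scaling_preserves_shape_and_total(self):
        cfg = AnalysisConfig()
        inactive = WindowStack("M", cfg)
        inactive.seqs = np.zeros((10, cfg.window_length), dtype=np.uint8)
        rng = np.random.default_rng(0)
        inactive.tracks["mutations"] = rng.integers(1, 10, cfg.window_length).astype(float)
        exp = inactive_background_profile(inactive, active_total_mutations=2001.0)
        assert exp.sum() == pytest.approx(2001.0)
        ratio = exp / inactive.tracks["mutations"]
        assert np.allclose(ratio, ratio[0])

    def test_empty_inactive_stack_errors(self):
        inactive = WindowStack("M", AnalysisConfig())
        with pytest.raises(ValueError):
            inactive_background_profile(inactive, 100.0)
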