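"""Conserved dipyrimidines and tetranucleotide-matched flank nulls."""

import numpy as np
import pandas as pd
import pytest

from uvtfbs.io_formats import encode_seq
from uvtfbs.within_motif import (
    PositionIndex,
    conserved_dipyrimidines,
    observed_site_count,
    percent_over_expected,
    sample_matched_expectation,
    sample_matched_positions,
    within_motif_repair,
)
from uvtfbs.window_stacking import AnalysisConfig, WindowStack

CFG = AnalysisConfig()
WL = CFG.window_length


def _stack_from_rows(rows: np.ndarray) -> WindowStack:
    stack = WindowStack("M", CFG)
    stack.seqs = rows.astype(np.uint8)
    n = rows.shape[0]
    stack.starts = np.arange(n, dtype=np.int64) * 3000
    stack.minus = np.zeros(n, dtype=bool)
    stack.chroms = ["chr1"] * n
    stack.window_mutations = np.zeros(n, dtype=np.int64)
    return stack


def _consensus_stack(motif_seq: str, n=20, seed=0) -> WindowStack:
    """Identical random windows with a fixed motif region sequence."""
    rng = np.random.default_rng(seed)
    row = rng.integers(0, 4, WL).astype(np.uint8)
    row[990:1011] = encode_seq(motif_seq)
    return _stack_from_rows(np.tile(row, (n, 1)))


def _enumerate_consensus_dipyrs(motif_seq: str):
    """Independent enumeration of the dipyrimidines of a consensus string."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out = set()
    for j in range(-10, 10):
        b1, b2 = motif_seq[j + 10], motif_seq[j + 11]
        if b1 in "CT" and b2 in "CT":
            out.add((j, "+", b1 + b2))
        if b1 in "AG" and b2 in "AG":
            out.add((j, "-", comp[b2] + comp[b1]))
    return out


class TestConservedDipyrimidines:
    def test_consensus_stack_matches_enumeration(self):
        motif_seq = "ACGTTAGGCATCCATAAGCTA"
        stack = _consensus_stack(motif_seq)
        sites = conserved_dipyrimidines(stack)
        got = {(s.offset, s.strand, s.dipyr) for s in sites}
        assert got == _enumerate_consensus_dipyrs(motif_seq)
        assert all(s.conservation == 1.0 for s in sites)

    def test_no_single_type_reaching_half_is_dropped(self):
        # 49% TT, 48% TC, 3% AA at the same offsets -> no site there
        rows = np.tile(encode_seq("A" * WL), (100, 1))
        rows[:49, 1000:1002] = encode_seq("TT")
        rows[49:97, 1000:1002] = encode_seq("TC")
        stack = _stack_from_rows(rows)
        sites = [s for s in conserved_dipyrimidines(stack) if s.offset == 0 and s.strand == "+"]
        assert sites == []

    def test_exactly_half_is_reported(self):
        rows = np.tile(encode_seq("A" * WL), (100, 1))
        rows[:50, 1000:1002] = encode_seq("TT")
        stack = _stack_from_rows(rows)
        sites = [s for s in conserved_dipyrimidines(stack)
                 if s.offset == 0 and s.strand == "+" and s.dipyr == "TT"]
        assert len(sites) == 1
        assert sites[0].conservation == pytest.approx(0.5)
        assert all(s.conservation >= 0.5 for s in conserved_dipyrimidines(stack))


class TestPercentOverExpected:
    @pytest.mark.parametrize(
        "obs,exp,out", [(15, 10, 50.0), (10, 10, 0.0), (0, 4, -100.0)]
    )
    def test_arithmetic(self, obs, exp, out):
        assert percent_over_expected(obs, exp) == pytest.approx(out)

    def test_zero_expected_missing(self):
        assert np.isnan(percent_over_expected(5, 0))


def _tiled_attg_stack(n=1) -> tuple[WindowStack, "np.ndarray"]:
    """Windows tiled with ATTG (so tetra ATTG recurs throughout the flanks)
    and the same ATTG planted at the motif center (site offset 0, strand +)."""
    unit = encode_seq("ATTG")
    row = np.tile(unit, WL // 4 + 1)[:WL].copy()
    row[999:1003] = encode_seq("ATTG")
    stack = _stack_from_rows(np.tile(row, (n, 1)))
    flank = stack.regions.masks["flanks"]
    tetra_pos = np.array([
        i for i in range(1, WL - 2)
        if flank[i] and flank[i + 1]
        and row[i - 1] == 0 and row[i] == 3 and row[i + 1] == 3 and row[i + 2] == 2
    ])
    return stack, tetra_pos


def _site_at_center(stack):
    sites = [s for s in conserved_dipyrimidines(stack)
             if s.offset == 0 and s.strand == "+" and s.dipyr == "TT"]
    assert len(sites) == 1
    return sites[0]


class TestMatchedSampling:
    def test_uniform_track_closed_form(self):
        """A mutation at every genomic base -> expected = 2 per carrying
        window, exactly, for any draw."""
        stack, _ = _tiled_attg_stack(n=5)
        site = _site_at_center(stack)
        rows = [("s", "chr1", int(p), "C", "T")
                for w in range(5) for p in range(w * 3000, w * 3000 + WL)]
        index = PositionIndex(pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt"]))
        expected, n_skipped = sample_matched_expectation(site, stack, index, n_iter=10, rng_seed=3)
        assert expected == pytest.approx(2.0 * 5)
        assert n_skipped == 0

    def test_draws_land_on_matching_tetranucleotides(self):
        stack, tetra_pos = _tiled_attg_stack(n=3)
        site = _site_at_center(stack)
        sampled = sample_matched_positions(site, stack, n_iter=20,
                                           rng=np.random.default_rng(0))
        assert sampled.window_idx.size == 3
        assert set(np.unique(sampled.oriented_index)) <= set(tetra_pos)
        assert not sampled.oriented_minus.any()

    def test_seed_stability(self):
        """Two seeds give expectations within 3 between-iteration SEMs."""
        rng = np.random.default_rng(9)
        stack, tetra_pos = _tiled_attg_stack(n=8)
        site = _site_at_center(stack)
        rows = []
        for w in range(8):
            for p in tetra_pos:
                c = int(rng.poisson(20))
                rows += [("chr1", int(w * 3000 + p), "+", c)]
        df = pd.DataFrame(rows, columns=["chrom", "pos5", "strand", "count"])
        index = PositionIndex(df)
        from uvtfbs.within_motif import sampled_track_sums

        s1 = sample_matched_positions(site, stack, 50, np.random.default_rng(1))
        s2 = sample_matched_positions(site, stack, 50, np.random.default_rng(2))
        sums1 = sampled_track_sums(s1, stack, index)
        sums2 = sampled_track_sums(s2, stack, index)
        sem = np.sqrt(sums1.var(ddof=1) / 50 + sums2.var(ddof=1) / 50)
        assert abs(sums1.mean() - sums2.mean()) < 3 * max(sem, 1e-9)

    def test_no_match_reports_missing(self):
        # motif tetra CTTC nowhere in the all-A flanks
        rows = np.tile(encode_seq("A" * WL), (4, 1))
        rows[:, 999:1003] = encode_seq("CTTC")
        stack = _stack_from_rows(rows)
        site = _site_at_center(stack)
        index = PositionIndex(pd.DataFrame(
            [("s", "chr1", 0, "C", "T")], columns=["sample", "chrom", "pos", "ref", "alt"]
        ))
        expected, n_skipped = sample_matched_expectation(site, stack, index, 10, 0)
        assert np.isnan(expected)
        assert n_skipped == 4


class TestWithinMotifRepair:
    def _indices(self, stack, tetra_pos, site_c0, site_c48, flank_c0, flank_c48):
        rows0 = [("chr1", 1000, "+", site_c0)]
        rows48 = [("chr1", 1000, "+", site_c48)]
        for p in tetra_pos:
            rows0.append(("chr1", int(p), "+", flank_c0))
            rows48.append(("chr1", int(p), "+", flank_c48))
        cols = ["chrom", "pos5", "strand", "count"]
        return (PositionIndex(pd.DataFrame(rows0, columns=cols)),
                PositionIndex(pd.DataFrame(rows48, columns=cols)))

    def test_identical_decay_gives_zero_pp(self):
        stack, tetra_pos = _tiled_attg_stack(n=1)
        site = _site_at_center(stack)
        i0, i48 = self._indices(stack, tetra_pos, 100, 60, 100, 60)
        pp = within_motif_repair(site, stack, i0, i48, (1000.0, 1000.0),
                                 rng=np.random.default_rng(0))
        assert pp == pytest.approx(0.0)

    def test_site_keeps_more_damage_than_flanks(self):
        """Site loses 20% of normalized CPDs, flanks lose 60% -> +40 pp."""
        stack, tetra_pos = _tiled_attg_stack(n=1)
        site = _site_at_center(stack)
        i0, i48 = self._indices(stack, tetra_pos, 100, 80, 100, 40)
        pp = within_motif_repair(site, stack, i0, i48, (1000.0, 1000.0),
                                 rng=np.random.default_rng(0))
        assert pp == pytest.approx(40.0)

    def test_zero_0h_signal_missing(self):
        stack, tetra_pos = _tiled_attg_stack(n=1)
        site = _site_at_center(stack)
        i0, i48 = self._indices(stack, tetra_pos, 0, 0, 100, 40)
        pp = within_motif_repair(site, stack, i0, i48, (1000.0, 1000.0),
                                 rng=np.random.default_rng(0))
        assert np.isnan(pp)


class TestObservedCount:
    def test_minus_orientation_window_maps_to_reference_coordinates(self):
        """A site on the motif '+' strand of a minus-orientation window sits
        on the reference '-' strand with the pair's leftmost base mirrored."""
        row = encode_seq("A" * WL)
        stack = _stack_from_rows(np.tile(row, (1, 1)))
        stack.seqs[0, 999:1003] = encode_seq("ATTG")
        stack.minus = np.array([True])
        site = _site_at_center(stack)
        # oriented pair indices (1000, 1001) -> genomic (start+999, start+1000);
        # leftmost = start + 999; oriented '+' on an inverted window = genomic '-'
        df = pd.DataFrame([("chr1", 999, "-", 7)],
                          columns=["chrom", "pos5", "strand", "count"])
        assert observed_site_count(site, stack, PositionIndex(df)) == 7
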