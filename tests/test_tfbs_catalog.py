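"""PWM construction, motif scanning, activity classification, jaccard."""

import numpy as np
import pytest

from uvtfbs.io_formats import GenomeSequence, GenomicInterval, encode_seq, revcomp_codes, decode_seq
from uvtfbs.tfbs_catalog import (
    BindingSite,
    MotifModel,
    build_pwm,
    classify_activity,
    jaccard_overlap,
    scan_motif,
)


def _motif_from_consensus(consensus: str, sharpness=0.97) -> MotifModel:
    L = len(consensus)
    counts = np.full((4, L), (1 - sharpness) / 3 * 100)
    for i, b in enumerate(consensus):
        counts["ACGT".index(b), i] = sharpness * 100
    return MotifModel("M1", "TF1", "fam", counts)


class TestBuildPwm:
    def test_pure_column_small_pseudocount_approaches_log2_4(self):
        counts = np.zeros((4, 4))
        counts[0] = 10  # all-A columns
        motif = MotifModel("M", "T", "f", counts)
        pwm = build_pwm(motif, pseudocount=1e-9)
        assert pwm.log_odds[0, 0] == pytest.approx(np.log2(4), abs=1e-6)

    def test_uniform_column_gives_zero(self):
        motif = MotifModel("M", "T", "f", np.ones((4, 4)))
        pwm = build_pwm(motif, pseudocount=0.8)
        assert np.allclose(pwm.log_odds, 0.0)

    def test_consensus_scores_max(self):
        motif = _motif_from_consensus("ACGTTGCA")
        pwm = build_pwm(motif)
        assert pwm.score("ACGTTGCA") == pytest.approx(pwm.max_score)
        assert pwm.max_score >= pwm.min_score

    def test_zero_column_rejected(self):
        counts = np.ones((4, 5))
        counts[:, 2] = 0
        with pytest.raises(ValueError):
            MotifModel("M", "T", "f", counts)


def _naive_best_hits(genome, peak, pwm, threshold):
    """Independent brute-force scorer: score every window on both strands."""
    seq = genome[peak.chrom][peak.start:peak.end]
    L = pwm.length
    hits = []
    for off in range(len(seq) - L + 1):
        window = seq[off:off + L]
        s_plus = pwm.score(window)
        rc = decode_seq(revcomp_codes(encode_seq(window)))
        s_minus = pwm.score(rc)
        if s_plus >= threshold:
            hits.append((peak.start + off, "+", s_plus))
        if s_minus >= threshold:
            hits.append((peak.start + off, "-", s_minus))
    return hits


class TestScanMotif:
    CONSENSUS = "ACGTACGGTACG"

    def setup_method(self):
        self.motif = _motif_from_consensus(self.CONSENSUS)
        self.pwm = build_pwm(self.motif)

    def test_plus_strand_consensus_found(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        seq = seq[:80] + self.CONSENSUS + seq[80 + len(self.CONSENSUS):]
        genome = GenomeSequence({"chr1": seq})
        sites = scan_motif(genome, [GenomicInterval("chr1", 60, 140)], self.pwm, 0.9)
        assert any(
            s.interval.start == 80 and s.interval.strand == "+"
            and s.score == pytest.approx(self.pwm.max_score)
            for s in sites
        )

    def test_reverse_complement_found_on_minus(self):
        rc = decode_seq(revcomp_codes(encode_seq(self.CONSENSUS)))
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        seq = seq[:80] + rc + seq[80 + len(rc):]
        genome = GenomeSequence({"chr1": seq})
        sites = scan_motif(genome, [GenomicInterval("chr1", 60, 140)], self.pwm, 0.9)
        assert any(s.interval.start == 80 and s.interval.strand == "-" for s in sites)

    def test_matches_naive_scorer_on_random_genome(self):
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        genome = GenomeSequence({"chr1": seq})
        peaks = [GenomicInterval("chr1", i, i + 100) for i in range(0, 2000, 100)]
        threshold = 0.5 * self.pwm.max_score  # low: plenty of hits
        naive = []
        for p in peaks:
            naive.extend(_naive_best_hits(genome, p, self.pwm, threshold))
        got = scan_motif(genome, peaks, self.pwm, 0.5)
        # every reported site appears in the naive list with identical score
        naive_set = {(pos, strand): s for pos, strand, s in naive}
        for site in got:
            key = (site.interval.start, site.interval.strand)
            assert key in naive_set
            assert site.score == pytest.approx(naive_set[key], abs=1e-9)
        # the best naive hit per peak is never better than the best reported
        for p in peaks:
            nh = [s for pos, st, s in _naive_best_hits(genome, p, self.pwm, threshold)]
            gh = [s.score for s in got
                  if p.start <= s.interval.start < p.end]
            if nh:
                assert gh and max(gh) == pytest.approx(max(nh), abs=1e-9)

    def test_planted_sites_recovered_exactly(self):
        rng = np.random.default_rng(9)
        codes = rng.integers(0, 4, 60_000).astype(np.uint8)
        positions = np.arange(50) * 1100 + 500
        cons = encode_seq(self.CONSENSUS)
        for p in positions:
            codes[p:p + cons.size] = cons
        genome = GenomeSequence({"chr1": codes})
        peaks = [GenomicInterval("chr1", int(p) - 40, int(p) + 52) for p in positions]
        sites = scan_motif(genome, peaks, self.pwm, 0.95)
        starts = sorted(s.interval.start for s in sites)
        assert starts == sorted(int(p) for p in positions)

    def test_short_peak_skipped(self):
        genome = GenomeSequence({"chr1": "ACGTACGT"})
        sites = scan_motif(genome, [GenomicInterval("chr1", 0, 5)], self.pwm, 0.9)
        assert sites == []

    def test_strand_symmetry_of_scores(self):
        """Scanning the reverse-complemented genome preserves the score multiset."""
        rng = np.random.default_rng(11)
        codes = rng.integers(0, 4, 500).astype(np.uint8)
        genome_f = GenomeSequence({"chr1": codes})
        genome_r = GenomeSequence({"chr1": revcomp_codes(codes)})
        peak = [GenomicInterval("chr1", 0, 500)]
        sf = scan_motif(genome_f, peak, self.pwm, 0.5)
        sr = scan_motif(genome_r, peak, self.pwm, 0.5)
        assert sorted(round(s.score, 9) for s in sf) == sorted(round(s.score, 9) for s in sr)


def _site(chrom, start, L=10):
    return BindingSite(GenomicInterval(chrom, start, start + L, "+"), "M", 1.0)


class TestClassifyActivity:
    def test_overlap_in_both_sets_active(self):
        sites = [_site("chr1", 100)]
        dhs1 = [GenomicInterval("chr1", 90, 120)]
        dhs2 = [GenomicInterval("chr1", 105, 106)]
        (out,) = classify_activity(sites, [dhs1, dhs2])
        assert out.active

    def test_overlap_in_one_of_two_sets_inactive(self):
        sites = [_site("chr1", 100)]
        dhs1 = [GenomicInterval("chr1", 90, 120)]
        dhs2 = [GenomicInterval("chr1", 500, 600)]
        (out,) = classify_activity(sites, [dhs1, dhs2])
        assert not out.active

    def test_empty_dhs_set_all_inactive(self):
        sites = [_site("chr1", 100)]
        (out,) = classify_activity(sites, [[]])
        assert not out.active

    def test_monotone_adding_intervals_never_deactivates(self):
        rng = np.random.default_rng(3)
        sites = [_site("chr1", int(s)) for s in rng.integers(0, 1000, 30)]
        base = [GenomicInterval("chr1", int(a), int(a) + 20)
                for a in rng.integers(0, 1000, 10)]
        extra = base + [GenomicInterval("chr1", int(a), int(a) + 20)
                        for a in rng.integers(0, 1000, 10)]
        active_base = [s.active for s in classify_activity(sites, [base])]
        active_more = [s.active for s in classify_activity(sites, [extra])]
        for b, m in zip(active_base, active_more):
            assert m or not b


class TestJaccard:
    def test_identical_sets_one(self):
        a = [_site("chr1", 100), _site("chr1", 400)]
        assert jaccard_overlap(a, a, pad=50) == pytest.approx(1.0)

    def test_disjoint_sets_zero(self):
        a = [_site("chr1", 100)]
        b = [_site("chr1", 5000)]
        assert jaccard_overlap(a, b, pad=50) == 0.0

    def test_known_arithmetic(self):
        # centers at 55 and 105 with pad 50 -> [5,106) and [55,156):
        # intersection 51, union 151
        a = [_site("chr1", 50, L=10)]
        b = [_site("chr1", 100, L=10)]
        assert jaccard_overlap(a, b, pad=50) == pytest.approx(51 / 151)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        a = [_site("chr1", int(s)) for s in rng.integers(0, 10_000, 40)]
        b = [_site("chr1", int(s)) for s in rng.integers(0, 10_000, 25)]
        assert jaccard_overlap(a, b) == pytest.approx(jaccard_overlap(b, a))
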