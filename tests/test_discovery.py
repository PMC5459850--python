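"""Coverage tracks, peak calling/pairing, hairpin folding, occurrence scan."""

import numpy as np
import pytest

from mirpeaks.core import GenomeInterval, MirnaAnnotation, RepeatRecord
from mirpeaks.discovery import (
    HairpinParams,
    Peak,
    PeakCallingParams,
    PremiRnaCandidate,
    RpmTrack,
    build_rpm_track,
    call_candidates,
    call_peaks,
    count_genome_occurrences,
    filter_candidates,
    find_occurrences,
    is_hairpin,
    make_param_grid,
    pair_double_peaks,
    tune_peak_params,
)
from .conftest import make_read


def track_from_values(values, chrom="chr1", strand="+", total=10**6, group="G"):
    return RpmTrack(group, total, {(chrom, strand): np.asarray(values, dtype=float)})


class TestBuildRpmTrack:
    def test_single_read_unit_rpm(self):
        track = build_rpm_track([make_read("chr1", 100, 119)], 10**6)
        values = track.rpm("chr1", "+")
        assert values[99:119].tolist() == [1.0] * 20
        assert values[:99].sum() == 0

    def test_two_identical_reads_add(self):
        reads = [make_read("chr1", 100, 119), make_read("chr1", 100, 119)]
        track = build_rpm_track(reads, 10**6)
        assert track.rpm("chr1", "+")[99:119].tolist() == [2.0] * 20

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            build_rpm_track([make_read("chr1", 1, 20)], 0)

    def test_matches_per_position_recount(self, rng):
        reads = [
            make_read("chr2", int(s), int(s) + int(l) - 1, strand=st)
            for s, l, st in zip(
                rng.integers(1, 960, 400), rng.integers(18, 28, 400),
                rng.choice(["+", "-"], 400),
            )
        ]
        total = 12345
        track = build_rpm_track(reads, total, chrom_lengths={"chr2": 1000})
        for strand in "+-":
            brute = np.zeros(1000)
            for read in reads:
                if read.interval.strand == strand:
                    brute[read.interval.start - 1 : read.interval.end] += 1
            np.testing.assert_allclose(track.rpm("chr2", strand), brute * 1e6 / total)


class TestCallPeaks:
    def test_all_zero_track(self):
        assert call_peaks(track_from_values(np.zeros(100))) == []

    def test_single_run(self):
        values = np.zeros(200)
        values[49:71] = 1.2  # positions 50..71, length 22
        (peak,) = call_peaks(track_from_values(values))
        assert peak.interval == GenomeInterval("chr1", 50, 71, "+")
        assert peak.interval.length == 22
        assert peak.max_height == pytest.approx(1.2)

    def test_threshold_is_inclusive(self):
        values = np.zeros(100)
        values[10:30] = 0.9
        peaks = call_peaks(track_from_values(values), min_height=0.9)
        assert len(peaks) == 1 and peaks[0].max_height == pytest.approx(0.9)

    def test_track_edges(self):
        values = np.ones(50)  # entire chromosome above threshold
        (peak,) = call_peaks(track_from_values(values))
        assert (peak.interval.start, peak.interval.end) == (1, 50)

    def test_equals_brute_force_scan(self, rng):
        """Maximal >=-threshold runs agree with a per-position python scan."""
        for _ in range(20):
            values = np.where(rng.random(800) < 0.15, rng.random(800) * 3, 0.0)
            track = track_from_values(values)
            called = {
                (p.interval.start, p.interval.end, round(p.max_height, 9))
                for p in call_peaks(track, 0.9)
            }
            brute = set()
            start = None
            for pos in range(len(values) + 1):
                above = pos < len(values) and values[pos] >= 0.9
                if above and start is None:
                    start = pos
                elif not above and start is not None:
                    brute.add(
                        (start + 1, pos, round(float(values[start:pos].max()), 9))
                    )
                    start = None
            assert called == brute


def peaks_at(*spans, chrom="chr1", strand="+", height=2.0):
    return [
        Peak(GenomeInterval(chrom, a, b, strand), height) for a, b in spans
    ]


class TestPairDoublePeaks:
    def test_textbook_pair(self):
        peaks = peaks_at((101, 122), (138, 159))  # lengths 22/22, gap 15
        assert pair_double_peaks(peaks) == [GenomeInterval("chr1", 101, 159, "+")]

    def test_gap_too_wide(self):
        peaks = peaks_at((101, 122), (158, 179))  # gap 35 > 30
        assert pair_double_peaks(peaks) == []

    def test_isolation_violated_by_third_peak(self):
        peaks = peaks_at((101, 122), (138, 159), (199, 220))  # third starts 40 nt after
        assert pair_double_peaks(peaks) == []

    def test_isolation_satisfied_at_fifty(self):
        peaks = peaks_at((101, 122), (138, 159), (210, 231))  # gap to third = 50
        assert pair_double_peaks(peaks) == [GenomeInterval("chr1", 101, 159, "+")]

    def test_peak_length_bounds(self):
        short = peaks_at((101, 117), (138, 159))  # left peak 17 nt < 18
        assert pair_double_peaks(short) == []
        long = peaks_at((101, 152), (170, 191))  # left peak 52 nt > 50
        assert pair_double_peaks(long) == []

    def test_emitted_pairs_satisfy_all_rules(self, rng):
        """Property: every emitted interval passes the four printed rules."""
        params = PeakCallingParams()
        for _ in range(50):
            cursor, peaks = 1, []
            for _ in range(int(rng.integers(2, 8))):
                cursor += int(rng.integers(1, 120))
                length = int(rng.integers(10, 60))
                peaks.append(Peak(GenomeInterval("chr1", cursor, cursor + length - 1, "+"), 1.0))
                cursor += length
            emitted = pair_double_peaks(peaks, params)
            spans = [(p.interval.start, p.interval.end) for p in peaks]
            for iv in emitted:
                left = next(p for p in peaks if p.interval.start == iv.start)
                right = next(p for p in peaks if p.interval.end == iv.end)
                assert params.peak_len_min <= left.interval.length <= params.peak_len_max
                assert params.peak_len_min <= right.interval.length <= params.peak_len_max
                gap = right.interval.start - left.interval.end - 1
                assert params.gap_min <= gap <= params.gap_max
                for other in peaks:
                    if other in (left, right):
                        continue
                    assert not (
                        left.interval.start - params.isolation
                        <= other.interval.end
                        and other.interval.start
                        <= right.interval.end + params.isolation
                    ), (spans, iv)
            # emitted intervals are disjoint
            for a, b in zip(emitted, emitted[1:]):
                assert a.end < b.start


# --- hairpin folding -------------------------------------------------------

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def brute_force_hairpin_pairs(seq: str) -> int:
    """Maximum pairs over all nested single-loop pairings, by direct
    enumeration of the outermost pair (independent of the DP recurrence)."""
    seq = seq.upper().replace("T", "U")

    def best(i: int, j: int) -> int:
        result = 0
        for a in range(i, j + 1):
            for b in range(a + 4, j + 1):  # loop >= 3 between a and b
                if (seq[a], seq[b]) in _PAIRS:
                    result = max(result, 1 + best(a + 1, b - 1))
        return result

    return best(0, len(seq) - 1)


class TestIsHairpin:
    def test_perfect_inverted_repeat(self):
        result = is_hairpin("GGGGGGGGAAAACCCCCCCC", min_stem_pairs=8)
        assert result.is_hairpin and result.n_pairs == 8

    def test_homopolymer_cannot_fold(self):
        result = is_hairpin("A" * 20)
        assert not result.is_hairpin and result.n_pairs == 0

    def test_structure_is_consistent(self):
        result = is_hairpin("GGGGGGGGAAAACCCCCCCC", min_stem_pairs=8)
        assert len(result.structure) == 20
        assert result.structure.count("(") == result.structure.count(")") == 8

    def test_gu_wobble_pairs_allowed(self):
        # G pairs U: stem of 6 GU pairs around a 4-nt loop
        result = is_hairpin("GGGGGGAAAAUUUUUU", min_stem_pairs=6)
        assert result.n_pairs == 6

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            is_hairpin("ACGTX")

    def test_matches_brute_force_enumeration(self, rng):
        """DP equals exhaustive single-hairpin enumeration for length <= 14."""
        bases = np.array(list("ACGU"))
        for length in (6, 9, 12, 14):
            for _ in range(15):
                seq = "".join(bases[rng.integers(0, 4, size=length)])
                assert is_hairpin(seq).n_pairs == brute_force_hairpin_pairs(seq), seq

    def test_pair_fraction_threshold(self):
        # 8 pairs in a 64-nt sequence: fraction 0.25 passes, 0.3 fails
        seq = "G" * 8 + "A" * 48 + "C" * 8
        assert is_hairpin(seq, min_stem_pairs=8, min_pair_fraction=0.25).is_hairpin
        assert not is_hairpin(seq, min_stem_pairs=8, min_pair_fraction=0.3).is_hairpin


class TestGenomeOccurrences:
    GENOME = {"chrA": "TTTT" + "ACGTACGTGGCC" + "TTTT", "chrB": "AAAA"}

    def test_single_occurrence(self):
        assert count_genome_occurrences("ACGTACGTGGCC", self.GENOME) == 1

    def test_absent_sequence(self):
        assert count_genome_occurrences("CCCGGGTTTAAA", self.GENOME) == 0

    def test_reverse_complement_counted(self):
        # revcomp of GGCCACGTACGT = ACGTACGTGGCC which is present
        assert count_genome_occurrences("GGCCACGTACGT", self.GENOME) == 1

    def test_multi_copy(self):
        genome = {"chr1": ("TTTTT" + "ACGGTCCAAGGT" + "TTTTT") * 16}
        assert count_genome_occurrences("ACGGTCCAAGGT", genome) == 16

    def test_palindrome_counted_once_per_position(self):
        genome = {"chr1": "AAAACGCGAAAA"}  # CGCG is its own revcomp
        assert count_genome_occurrences("CGCG", genome) == 1

    def test_occurrence_intervals(self):
        hits = find_occurrences("ACGTACGTGGCC", self.GENOME)
        assert hits == [GenomeInterval("chrA", 5, 16, "+")]


class TestFilterCandidates:
    HAIRPIN = "GCGCGCGCGCGCGCAUAUAUAUGCGCGCGCGCGCGC".replace("U", "T")

    def _candidate(self, chrom, start, end, strand="+"):
        iv = GenomeInterval(chrom, start, end, strand)
        peak = Peak(iv, 2.0)
        return PremiRnaCandidate(iv, peak, peak)

    def _genome(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        background = "".join(bases[rng.integers(0, 4, 3000)])
        return {"chr1": background[:1000] + self.HAIRPIN + background[1000:]}

    def test_known_overlap_rejected_any_strand(self):
        genome = self._genome()
        known = [
            MirnaAnnotation(
                "k1", "pre_mirna", GenomeInterval("chr1", 1036, 1100, "-")
            )
        ]
        cand = self._candidate("chr1", 1001, 1036)  # 1-nt overlap, other strand
        assert filter_candidates([cand], known, [], genome) == []

    def test_repeat_overlap_rejected(self):
        genome = self._genome()
        repeats = [RepeatRecord(GenomeInterval("chr1", 1036, 1100, "+"), "snRNA")]
        cand = self._candidate("chr1", 1001, 1036)
        assert filter_candidates([cand], [], repeats, genome) == []

    def test_planted_hairpin_retained_with_annotations(self):
        genome = self._genome()
        cand = self._candidate("chr1", 1001, 1036)
        (kept,) = filter_candidates(
            [cand], [], [], genome, hairpin_params=HairpinParams(min_stem_pairs=10)
        )
        assert kept.hairpin.is_hairpin
        assert kept.sequence == self.HAIRPIN
        assert kept.genome_occurrences == 1
        assert kept.id  # assigned a stable id

    def test_non_hairpin_rejected(self):
        genome = {"chr1": "A" * 2000}
        cand = self._candidate("chr1", 1001, 1040)
        assert filter_candidates([cand], [], [], genome) == []

    def test_occurrence_boundary_fifteen_vs_sixteen(self):
        unit = "TTTTT" + self.HAIRPIN + "TTTTT"
        for copies, expected in ((15, 1), (16, 0)):
            genome = {"chr1": unit * copies}
            cand = self._candidate("chr1", 6, 5 + len(self.HAIRPIN))
            kept = filter_candidates(
                [cand], [], [], genome, hairpin_params=HairpinParams(min_stem_pairs=10)
            )
            assert len(kept) == expected, copies


def test_discovery_is_translation_equivariant(rng):
    """Shifting all reads by +k shifts every candidate interval by +k."""
    starts = np.sort(rng.integers(1000, 5000, 6))
    reads = []
    for locus_start in starts[:3]:
        for arm in (0, 40):
            for _ in range(5):
                s = int(locus_start) + arm
                reads.append(make_read("chr1", s, s + 21))
    k = 137
    shifted = [make_read("chr1", r.interval.start + k, r.interval.end + k) for r in reads]
    track = build_rpm_track(reads, 10**6, chrom_lengths={"chr1": 10_000})
    track_shifted = build_rpm_track(shifted, 10**6, chrom_lengths={"chr1": 10_000})
    params = PeakCallingParams()
    original = [c.interval for c in call_candidates(track, params)]
    moved = [c.interval for c in call_candidates(track_shifted, params)]
    assert moved == [iv.shifted(k) for iv in original]


class TestTunePeakParams:
    def _expressed_track(self):
        values = np.zeros(2000)
        values[499:521] = 5.0   # arm peaks at 500..521 and 540..561
        values[539:561] = 5.0
        track = track_from_values(values)
        known = [GenomeInterval("chr1", 500, 561, "+")]
        return track, known

    def test_single_point_grid(self):
        track, known = self._expressed_track()
        grid = make_param_grid()
        result = tune_peak_params([track], known, grid)
        assert result.params == grid[0]
        assert result.n_recovered == 1
        assert result.recovery_fraction == 1.0

    def test_empty_grid_rejected(self):
        track, known = self._expressed_track()
        with pytest.raises(ValueError, match="empty"):
            tune_peak_params([track], known, [])

    def test_no_expressed_known_returns_first_point(self):
        track, _ = self._expressed_track()
        grid = make_param_grid(min_heights=(0.9, 1.8))
        result = tune_peak_params([track], [], grid)
        assert result.n_recovered == 0 and result.n_expressed == 0
        assert result.recovery_fraction == 0.0

    def test_recovering_params_beat_blind_params(self):
        track, known = self._expressed_track()
        blind = PeakCallingParams(gap_min=25, gap_max=30)  # true gap is 18
        good = PeakCallingParams()
        result = tune_peak_params([track], known, [blind, good])
        assert result.params == good
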