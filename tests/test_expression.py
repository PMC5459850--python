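"""Counting, RPM normalization, shoulder splitting and duplicate merging."""

import numpy as np
import pytest

from mirpeaks.core import GenomeInterval, ReadIndex, reads_to_frame
from mirpeaks.discovery import Peak, PremiRnaCandidate
from mirpeaks.expression import (
    Feature,
    build_expression_matrix,
    count_interval_reads,
    merge_duplicate_expression,
    rpm_normalize,
    split_shoulders,
)
from .conftest import make_read


class TestCountIntervalReads:
    INTERVAL = GenomeInterval("chr1", 100, 150, "+")

    def test_border_read_counts_once(self):
        assert count_interval_reads([make_read("chr1", 95, 115)], self.INTERVAL) == 1

    def test_wrong_strand_not_counted(self):
        assert count_interval_reads([make_read("chr1", 110, 130, strand="-")],
                                    self.INTERVAL) == 0

    def test_single_base_touch_counts(self):
        assert count_interval_reads([make_read("chr1", 80, 100)], self.INTERVAL) == 1
        assert count_interval_reads([make_read("chr1", 150, 170)], self.INTERVAL) == 1
        assert count_interval_reads([make_read("chr1", 79, 99)], self.INTERVAL) == 0
        assert count_interval_reads([make_read("chr1", 151, 171)], self.INTERVAL) == 0

    def test_matches_brute_force(self, rng):
        reads = [
            make_read("chr1", int(s), int(s) + int(l) - 1, strand=st)
            for s, l, st in zip(
                rng.integers(1, 2000, 500), rng.integers(15, 35, 500),
                rng.choice(["+", "-"], 500),
            )
        ]
        index = ReadIndex(reads_to_frame(reads))
        for _ in range(50):
            a = int(rng.integers(1, 1900))
            b = a + int(rng.integers(1, 120))
            strand = str(rng.choice(["+", "-"]))
            query = GenomeInterval("chr1", a, b, strand)
            brute = sum(1 for r in reads if r.interval.overlaps(query))
            assert index.count(query) == brute

    def test_nested_interval_monotonicity(self, rng):
        reads = [
            make_read("chr1", int(s), int(s) + 21)
            for s in rng.integers(1, 1000, 200)
        ]
        inner = GenomeInterval("chr1", 400, 450, "+")
        outer = GenomeInterval("chr1", 380, 470, "+")
        assert count_interval_reads(reads, inner) <= count_interval_reads(reads, outer)


class TestRpmNormalize:
    def test_worked_example(self):
        assert rpm_normalize(9, 3_000_000) == 3.0

    def test_zero_raw(self):
        assert rpm_normalize(0, 10) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            rpm_normalize(5, 0)

    def test_linearity(self, rng):
        total = 777_777
        for raw in rng.integers(0, 10_000, 20):
            assert rpm_normalize(2 * int(raw), total) == pytest.approx(
                2 * rpm_normalize(int(raw), total)
            )


class TestSplitShoulders:
    def test_fifty_nt_not_split(self):
        assert split_shoulders(GenomeInterval("chr1", 1, 50, "+")) is None

    def test_fifty_one_nt_split(self):
        pair = split_shoulders(GenomeInterval("chr1", 1, 51, "+"))
        assert (pair.left.start, pair.left.end) == (1, 25)
        assert (pair.right.start, pair.right.end) == (26, 51)
        assert pair.left.length == 25 and pair.right.length == 26

    def test_halves_tile_parent(self):
        parent = GenomeInterval("chr2", 1000, 1080, "-")
        pair = split_shoulders(parent)
        assert pair.left.end + 1 == pair.right.start
        assert pair.left.length + pair.right.length == parent.length
        assert pair.left.length == parent.length // 2

    def test_strand_assigns_labels(self):
        plus = split_shoulders(GenomeInterval("chr1", 1, 60, "+"))
        minus = split_shoulders(GenomeInterval("chr1", 1, 60, "-"))
        assert (plus.left_label, plus.right_label) == ("5p", "3p")
        assert (minus.left_label, minus.right_label) == ("3p", "5p")


class TestExpressionMatrix:
    def test_single_feature_counts_and_rpm(self):
        feature = Feature("f1", GenomeInterval("chr1", 100, 150, "+"))
        reads = [make_read("chr1", 95, 115), make_read("chr1", 120, 140),
                 make_read("chr1", 149, 170)]
        matrix = build_expression_matrix([feature], {"S1": reads}, {"S1": 10**6})
        assert matrix.raw.at["f1", "S1"] == 3
        assert matrix.rpm.at["f1", "S1"] == 3.0

    def test_empty_feature_list(self):
        matrix = build_expression_matrix([], {"S1": []}, {"S1": 100})
        assert matrix.raw.shape == (0, 1)
        assert matrix.samples == ["S1"]
        assert matrix.informative_totals == {"S1": 100}

    def test_duplicate_feature_ids_rejected(self):
        iv = GenomeInterval("chr1", 1, 30, "+")
        with pytest.raises(ValueError, match="duplicate"):
            build_expression_matrix(
                [Feature("f", iv), Feature("f", iv)], {"S1": []}, {"S1": 1}
            )

    def test_rpm_identity_holds_bit_for_bit(self, rng):
        features = [
            Feature(f"f{i}", GenomeInterval("chr1", int(s), int(s) + 60, "+"))
            for i, s in enumerate(rng.integers(1, 5000, 25))
        ]
        reads = {
            "A": [make_read("chr1", int(s), int(s) + 21, sample="A")
                  for s in rng.integers(1, 5000, 800)],
            "B": [make_read("chr1", int(s), int(s) + 21, sample="B")
                  for s in rng.integers(1, 5000, 400)],
        }
        totals = {"A": 800, "B": 417}
        matrix = build_expression_matrix(features, reads, totals)
        assert matrix.recompute_rpm().equals(matrix.rpm)

    def test_informative_variant_never_exceeds_all_reads(self, rng):
        """Counting only informative reads can only lower each cell."""
        all_reads = [
            make_read("chr1", int(s), int(s) + int(l) - 1)
            for s, l in zip(rng.integers(1, 3000, 400), rng.integers(15, 35, 400))
        ]
        informative = [r for r in all_reads if 18 <= r.length <= 27]
        features = [
            Feature(f"f{i}", GenomeInterval("chr1", int(s), int(s) + 70, "+"))
            for i, s in enumerate(rng.integers(1, 2900, 15))
        ]
        totals = {"S1": len(informative)}
        m_all = build_expression_matrix(features, {"S1": all_reads}, totals)
        m_inf = build_expression_matrix(
            features, {"S1": informative}, totals, counting_mode="informative_reads"
        )
        assert (m_inf.raw.to_numpy() <= m_all.raw.to_numpy()).all()


class TestMergeDuplicateExpression:
    SEQ = "GGGCCGCGCGCAAAGCGCGCGGTTT"

    def _candidate(self, cid, chrom, start, seq):
        iv = GenomeInterval(chrom, start, start + len(seq) - 1, "+")
        peak = Peak(iv, 2.0)
        return PremiRnaCandidate(iv, peak, peak, id=cid, sequence=seq)

    def test_exact_duplicates_merged_with_summed_counts(self):
        genome = {"chr1": "T" * 100 + self.SEQ + "T" * 100 + self.SEQ + "T" * 100}
        cand_a = self._candidate("a", "chr1", 101, self.SEQ)
        cand_b = self._candidate("b", "chr1", 226, self.SEQ)
        reads = {
            "S1": [make_read("chr1", 101, 122), make_read("chr1", 226, 247)],
        }
        matrix = build_expression_matrix(
            [Feature("a", cand_a.interval), Feature("b", cand_b.interval)],
            reads, {"S1": 10**6},
        )
        merged = merge_duplicate_expression([cand_a, cand_b], genome, matrix)
        assert [f.id for f in merged.features] == ["a+b"]
        assert merged.raw.at["a+b", "S1"] == 2
        assert merged.rpm.at["a+b", "S1"] == 2.0

    def test_disjoint_candidates_unchanged(self):
        other = "ATCGATCGGCTAGCTAACGATCGAT"
        genome = {"chr1": "T" * 100 + self.SEQ + "T" * 100 + other + "T" * 100}
        cand_a = self._candidate("a", "chr1", 101, self.SEQ)
        cand_b = self._candidate("b", "chr1", 226, other)
        matrix = build_expression_matrix(
            [Feature("a", cand_a.interval), Feature("b", cand_b.interval)],
            {"S1": [make_read("chr1", 101, 122)]}, {"S1": 10**6},
        )
        merged = merge_duplicate_expression([cand_a, cand_b], genome, matrix)
        assert sorted(f.id for f in merged.features) == ["a", "b"]
        assert merged.raw.at["a", "S1"] == 1
        assert merged.raw.at["b", "S1"] == 0


def test_shoulder_counts_bounded_by_parent(rng):
    """Each half's count <= parent count <= l + r (reads may straddle)."""
    parent = GenomeInterval("chr1", 1000, 1080, "+")
    reads = [
        make_read("chr1", int(s), int(s) + 21)
        for s in rng.integers(950, 1100, 300)
    ]
    pair = split_shoulders(parent)
    n_parent = count_interval_reads(reads, parent)
    n_left = count_interval_reads(reads, pair.left)
    n_right = count_interval_reads(reads, pair.right)
    assert n_left <= n_parent and n_right <= n_parent
    assert n_parent <= n_left + n_right
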