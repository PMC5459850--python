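"""Novel pre-miRNA discovery from strand-aware RPM coverage double peaks.

Dicer processing leaves sequencing reads stacked on the two arms of a
pre-miRNA hairpin, which shows up in a coverage track as two close peaks
separated by a low-coverage loop. This module builds per-group RPM coverage
tracks from informative reads, calls threshold peaks, pairs them into
double-peak candidate loci, and filters candidates against known miRNAs,
RNA-class repeats, a hairpin-structure requirement and a genome-occurrence
cap. A small grid search tunes the calling parameters by maximising recovery
of expressed known pre-miRNAs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    GenomeInterval,
    MappedRead,
    MirnaAnnotation,
    RepeatRecord,
    reads_to_frame,
    reverse_complement,
)
from .preprocess import DEFAULT_EXCLUDED_REPEAT_CLASSES

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# RPM coverage tracks


class RpmTrack:
    """Per-position, per-strand RPM coverage for one sample group.

    Values are (read overlap count) * 1e6 / group informative total; array
    index 0 corresponds to genomic position 1.
    """

    def __init__(
        self,
        group_id: str,
        group_informative_total: int,
        coverage: dict[tuple[str, str], np.ndarray],
    ):
        if group_informative_total <= 0:
            raise ValueError("group_informative_total must be positive")
        self.group_id = group_id
        self.group_informative_total = group_informative_total
        self.coverage = coverage

    def rpm(self, chrom: str, strand: str) -> np.ndarray:
        return self.coverage.get((chrom, strand), np.zeros(0))

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self.coverage)


def build_rpm_track(
    reads: Sequence[MappedRead] | pd.DataFrame,
    group_informative_total: int,
    *,
    group_id: str = "group",
    chrom_lengths: Mapping[str, int] | None = None,
) -> RpmTrack:
    """Pool a group's informative reads into a per-position RPM track.

    The value at position p is the number of same-strand reads covering p,
    scaled by 1e6 over the group's informative-read total. Chromosome sizes
    default to the largest read end seen per chromosome.
    """
    if group_informative_total <= 0:
        raise ValueError("group_informative_total must be positive")
    frame = reads if isinstance(reads, pd.DataFrame) else reads_to_frame(reads)
    scale = 1e6 / group_informative_total
    coverage: dict[tuple[str, str], np.ndarray] = {}
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            for strand in "+-":
                coverage[(chrom, strand)] = np.zeros(length)
    for (chrom, strand), sub in frame.groupby(["chrom", "strand"], observed=True):
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        length = (
            chrom_lengths[str(chrom)] if chrom_lengths else int(ends.max())
        )
        diff = np.zeros(length + 1)
        np.add.at(diff, starts - 1, 1.0)
        np.add.at(diff, ends, -1.0)
        coverage[(str(chrom), str(strand))] = np.cumsum(diff[:-1]) * scale
    return RpmTrack(group_id, group_informative_total, coverage)


# ---------------------------------------------------------------------------
# Peak calling and pairing


@dataclass(frozen=True)
class Peak:
    """A maximal run of positions at or above the calling threshold."""

    interval: GenomeInterval
    max_height: float


@dataclass(frozen=True)
class PeakCallingParams:
    """The four printed double-peak parameters plus the calling threshold."""

    min_height: float = 0.9      # RPM; threshold is inclusive
    peak_len_min: int = 18       # nt
    peak_len_max: int = 50       # nt
    gap_min: int = 8             # nt between inner peak edges
    gap_max: int = 30
    isolation: int = 50          # nt free of other peaks around the pair

    def __post_init__(self) -> None:
        if min(self.min_height, self.peak_len_min, self.gap_min, self.isolation) <= 0:
            raise ValueError("all peak-calling parameters must be positive")
        if self.peak_len_min > self.peak_len_max:
            raise ValueError("peak_len_min > peak_len_max")
        if self.gap_min > self.gap_max:
            raise ValueError("gap_min > gap_max")


@dataclass(frozen=True)
class HairpinResult:
    is_hairpin: bool
    n_pairs: int
    structure: str


@dataclass
class PremiRnaCandidate:
    """A called double-peak locus with its sequence and quality annotations."""

    interval: GenomeInterval
    left_peak: Peak
    right_peak: Peak
    id: str = ""
    group_id: str = ""
    sequence: str = ""
    hairpin: HairpinResult | None = None
    genome_occurrences: int = 0
    tier: str | None = None
    tier_scores: "object | None" = None  # filled by mirpeaks.tiering


def call_peaks(track: RpmTrack, min_height: float = 0.9) -> list[Peak]:
    """Call every maximal run of consecutive positions with RPM >= threshold.

    Peaks are disjoint by construction and returned sorted by (chrom, strand,
    start).
    """
    peaks: list[Peak] = []
    for chrom, strand in track.keys():
        values = track.coverage[(chrom, strand)]
        above = values >= min_height
        if not above.any():
            continue
        # run starts are where `above` switches on; run ends where it switches off
        run_starts = np.flatnonzero(above & ~np.roll(above, 1))
        if above[0]:
            run_starts = np.unique(np.concatenate(([0], run_starts)))
        run_ends = np.flatnonzero(above & ~np.roll(above, -1))
        if above[-1]:
            run_ends = np.unique(np.concatenate((run_ends, [len(above) - 1])))
        for a, b in zip(run_starts, run_ends):
            peaks.append(
                Peak(
                    interval=GenomeInterval(chrom, int(a) + 1, int(b) + 1, strand),
                    max_height=float(values[a : b + 1].max()),
                )
            )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.strand, p.interval.start))
    return peaks


def _pair_double_peaks(
    peaks: Sequence[Peak], params: PeakCallingParams
) -> list[tuple[GenomeInterval, Peak, Peak]]:
    """Pair adjacent peaks into double-peak loci (detailed records).

    A pair (L, R) is emitted when both peak lengths fall in
    [peak_len_min, peak_len_max], the valley width R.start - L.end - 1 falls
    in [gap_min, gap_max], and no third peak sits closer than ``isolation``
    nt to either flank of the pair. Emitted intervals are disjoint (a peak
    joins at most one emitted pair, scanning left to right).
    """
    out: list[tuple[GenomeInterval, Peak, Peak]] = []
    i = 0
    while i < len(peaks) - 1:
        left, right = peaks[i], peaks[i + 1]
        li, ri = left.interval, right.interval
        if li.chrom != ri.chrom or li.strand != ri.strand:
            i += 1
            continue
        ok = (
            params.peak_len_min <= li.length <= params.peak_len_max
            and params.peak_len_min <= ri.length <= params.peak_len_max
            and params.gap_min <= ri.start - li.end - 1 <= params.gap_max
        )
        if ok and i > 0:
            prev = peaks[i - 1].interval
            if prev.chrom == li.chrom and prev.strand == li.strand:
                ok = li.start - prev.end - 1 >= params.isolation
        if ok and i + 2 < len(peaks):
            nxt = peaks[i + 2].interval
            if nxt.chrom == ri.chrom and nxt.strand == ri.strand:
                ok = nxt.start - ri.end - 1 >= params.isolation
        if ok:
            out.append(
                (GenomeInterval(li.chrom, li.start, ri.end, li.strand), left, right)
            )
            i += 2
        else:
            i += 1
    return out


def pair_double_peaks(
    peaks: Sequence[Peak], params: PeakCallingParams | None = None
) -> list[GenomeInterval]:
    """Emit the candidate interval [left.start, right.end] per valid pair."""
    return [iv for iv, _, _ in _pair_double_peaks(peaks, params or PeakCallingParams())]


def call_candidates(
    track: RpmTrack, params: PeakCallingParams | None = None
) -> list[PremiRnaCandidate]:
    """Full caller for one group: peaks then double-peak pairing."""
    params = params or PeakCallingParams()
    peaks = call_peaks(track, params.min_height)
    candidates = []
    by_key: dict[tuple[str, str], list[Peak]] = {}
    for peak in peaks:
        by_key.setdefault((peak.interval.chrom, peak.interval.strand), []).append(peak)
    for key in sorted(by_key):
        for interval, left, right in _pair_double_peaks(by_key[key], params):
            candidates.append(
                PremiRnaCandidate(
                    interval=interval,
                    left_peak=left,
                    right_peak=right,
                    group_id=track.group_id,
                )
            )
    return candidates


def union_candidates(
    candidate_sets: Iterable[Sequence[PremiRnaCandidate]],
) -> list[PremiRnaCandidate]:
    """Union per-group candidate loci by same-strand interval overlap.

    Overlapping loci collapse to the maximum of their spans; the peak
    annotations of the highest-peaked contributor are kept.
    """
    pool = sorted(
        (c for cs in candidate_sets for c in cs),
        key=lambda c: (c.interval.chrom, c.interval.strand, c.interval.start),
    )
    merged: list[PremiRnaCandidate] = []
    for cand in pool:
        if merged and cand.interval.overlaps(merged[-1].interval):
            prev = merged[-1]
            interval = GenomeInterval(
                prev.interval.chrom,
                min(prev.interval.start, cand.interval.start),
                max(prev.interval.end, cand.interval.end),
                prev.interval.strand,
            )
            best = max(
                (prev, cand), key=lambda c: max(c.left_peak.max_height, c.right_peak.max_height)
            )
            merged[-1] = replace(
                best,
                interval=interval,
                group_id="+".join(sorted({prev.group_id, cand.group_id} - {""})),
            )
        else:
            merged.append(replace(cand))
    return merged


# ---------------------------------------------------------------------------
# Hairpin folding (single-hairpin base-pair maximisation)

_PAIRABLE = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)
_MIN_LOOP = 3


def _pairable(a: str, b: str) -> bool:
    return (a, b) in _PAIRABLE


def is_hairpin(
    sequence: str, min_stem_pairs: int = 14, min_pair_fraction: float = 0.25
) -> HairpinResult:
    """Judge whether a sequence folds into a single stem-loop.

    Maximises the number of base pairs over all single-hairpin structures --
    fully nested pair chains with one terminal loop of >= 3 nt, Watson-Crick
    plus GU wobble pairs -- by an O(n^2) dynamic program, then applies the
    two thresholds: at least ``min_stem_pairs`` pairs and a paired-base
    fraction (2*pairs/length) of at least ``min_pair_fraction``. An external
    thermodynamic folding engine can be plugged in behind the same contract.
    """
    seq = sequence.upper().replace("T", "U")
    if any(base not in "ACGU" for base in seq):
        bad = sorted(set(seq) - set("ACGU"))
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    n = len(seq)
    if n < 2:
        return HairpinResult(False, 0, "." * n)
    # best[i][j]: max pairs of a nested single-loop chain within seq[i..j]
    best = np.zeros((n, n), dtype=np.int32)
    for span in range(_MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            value = max(best[i + 1, j], best[i, j - 1])
            if _pairable(seq[i], seq[j]):
                inner = best[i + 1, j - 1] if span >= _MIN_LOOP + 2 else 0
                value = max(value, 1 + inner)
            best[i, j] = value
    n_pairs = int(best[0, n - 1])
    structure = ["."] * n
    i, j = 0, n - 1
    while i < j:
        if _pairable(seq[i], seq[j]) and j - i - 1 >= _MIN_LOOP:
            inner = best[i + 1, j - 1] if j - 1 >= i + 1 else 0
            if best[i, j] == 1 + inner:
                structure[i], structure[j] = "(", ")"
                i, j = i + 1, j - 1
                continue
        if best[i, j] == best[i + 1, j]:
            i += 1
        else:
            j -= 1
    verdict = n_pairs >= min_stem_pairs and 2 * n_pairs / n >= min_pair_fraction
    return HairpinResult(verdict, n_pairs, "".join(structure))


# ---------------------------------------------------------------------------
# Genome occurrence scan


def _find_forward(haystack: str, needle: str) -> list[int]:
    hits, pos = [], haystack.find(needle)
    while pos != -1:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)
    return hits


def find_occurrences(sequence: str, genome: Mapping[str, str]) -> list[GenomeInterval]:
    """Exact occurrences of a sequence or its reverse complement, genome-wide.

    Overlapping matches count separately; a palindromic sequence is counted
    once per position. Matching is on the DNA alphabet (U folded to T).
    """
    seq = sequence.upper().replace("U", "T")
    rc = reverse_complement(seq)
    occurrences: list[GenomeInterval] = []
    for chrom, chrom_seq in genome.items():
        chrom_seq = chrom_seq.upper()
        for pos in _find_forward(chrom_seq, seq):
            occurrences.append(GenomeInterval(chrom, pos + 1, pos + len(seq), "+"))
        if rc != seq:
            for pos in _find_forward(chrom_seq, rc):
                occurrences.append(GenomeInterval(chrom, pos + 1, pos + len(seq), "-"))
    return occurrences


def count_genome_occurrences(sequence: str, genome: Mapping[str, str]) -> int:
    """Number of exact genome-wide occurrences (both strands)."""
    return len(find_occurrences(sequence, genome))


def extract_sequence(genome: Mapping[str, str], interval: GenomeInterval) -> str:
    """Strand-oriented genomic sequence of an interval (5'->3')."""
    raw = genome[interval.chrom][interval.start - 1 : interval.end].upper()
    return reverse_complement(raw) if interval.strand == "-" else raw


# ---------------------------------------------------------------------------
# Candidate filtering


@dataclass(frozen=True)
class HairpinParams:
    min_stem_pairs: int = 14
    min_pair_fraction: float = 0.25


def filter_candidates(
    candidates: Sequence[PremiRnaCandidate],
    known: Iterable[MirnaAnnotation],
    repeats: Iterable[RepeatRecord],
    genome: Mapping[str, str],
    *,
    max_occurrences: int = 15,
    hairpin_params: HairpinParams | None = None,
    excluded_repeat_classes: frozenset[str] = DEFAULT_EXCLUDED_REPEAT_CLASSES,
) -> list[PremiRnaCandidate]:
    """Apply the four candidate filters and annotate survivors.

    Dropped: candidates overlapping a known pre-miRNA (either strand),
    overlapping an RNA-class repeat, failing the hairpin test, or whose
    sequence occurs more than ``max_occurrences`` times genome-wide.
    Survivors carry their strand-oriented sequence, hairpin annotation,
    occurrence count and a stable id.
    """
    hairpin_params = hairpin_params or HairpinParams()
    known_pre = [ann.interval for ann in known if ann.kind == "pre_mirna"]
    excluded_repeats = [
        r.interval for r in repeats if r.repeat_class in excluded_repeat_classes
    ]
    retained: list[PremiRnaCandidate] = []
    n_known = n_repeat = n_fold = n_occ = 0
    for cand in candidates:
        if any(cand.interval.overlaps(iv, ignore_strand=True) for iv in known_pre):
            n_known += 1
            continue
        if any(cand.interval.overlaps(iv, ignore_strand=True) for iv in excluded_repeats):
            n_repeat += 1
            continue
        sequence = extract_sequence(genome, cand.interval)
        hairpin = is_hairpin(
            sequence, hairpin_params.min_stem_pairs, hairpin_params.min_pair_fraction
        )
        if not hairpin.is_hairpin:
            n_fold += 1
            continue
        occurrences = count_genome_occurrences(sequence, genome)
        if occurrences > max_occurrences:
            n_occ += 1
            continue
        cand.sequence = sequence
        cand.hairpin = hairpin
        cand.genome_occurrences = occurrences
        retained.append(cand)
    for rank, cand in enumerate(retained, start=1):
        if not cand.id:
            cand.id = f"cand-{rank:04d}"
    logger.info(
        "candidate filters: %d in -> %d retained (%d known-overlap, %d repeat, "
        "%d non-hairpin, %d multi-copy)",
        len(candidates), len(retained), n_known, n_repeat, n_fold, n_occ,
    )
    return retained


# ---------------------------------------------------------------------------
# Parameter tuning


@dataclass(frozen=True)
class PeakTuningResult:
    params: PeakCallingParams
    n_recovered: int
    n_expressed: int

    @property
    def recovery_fraction(self) -> float:
        return self.n_recovered / self.n_expressed if self.n_expressed else 0.0


def make_param_grid(
    min_heights: Sequence[float] = (0.9,),
    peak_len_bounds: Sequence[tuple[int, int]] = ((18, 50),),
    gap_bounds: Sequence[tuple[int, int]] = ((8, 30),),
    isolations: Sequence[int] = (50,),
) -> list[PeakCallingParams]:
    return [
        PeakCallingParams(h, pl[0], pl[1], g[0], g[1], iso)
        for h, pl, g, iso in itertools.product(
            min_heights, peak_len_bounds, gap_bounds, isolations
        )
    ]


def tune_peak_params(
    tracks: Sequence[RpmTrack],
    known_expressed: Sequence[GenomeInterval],
    grid: Sequence[PeakCallingParams],
) -> PeakTuningResult:
    """Grid-search calling parameters to maximise known pre-miRNA recovery.

    A known pre-miRNA counts as recovered when any called candidate overlaps
    it on the same strand. Ties prefer a stricter (higher) threshold, then a
    smaller peak-length/gap search window, then grid order.
    """
    if not grid:
        raise ValueError("parameter grid is empty")
    peak_cache: dict[float, list[list[Peak]]] = {}

    def peaks_for(min_height: float) -> list[list[Peak]]:
        if min_height not in peak_cache:
            peak_cache[min_height] = [call_peaks(t, min_height) for t in tracks]
        return peak_cache[min_height]

    best: tuple | None = None
    for order, params in enumerate(grid):
        recovered = 0
        candidate_sets = []
        for peaks in peaks_for(params.min_height):
            by_key: dict[tuple[str, str], list[Peak]] = {}
            for peak in peaks:
                by_key.setdefault(
                    (peak.interval.chrom, peak.interval.strand), []
                ).append(peak)
            for key in by_key:
                candidate_sets.extend(pair_double_peaks(by_key[key], params))
        for iv in known_expressed:
            if any(iv.overlaps(c) for c in candidate_sets):
                recovered += 1
        window = (params.peak_len_max - params.peak_len_min) + (
            params.gap_max - params.gap_min
        )
        key = (-recovered, -params.min_height, window, order)
        if best is None or key < best[0]:
            best = (key, params, recovered)
    _, params, recovered = best
    return PeakTuningResult(params, recovered, len(known_expressed))
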