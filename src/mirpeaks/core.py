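"""Shared genomic coordinate types and small sequence utilities.

Every coordinate in this package is 1-based and closed on both ends, the
convention used by miRBase GFF3 annotation. The only place other conventions
appear is the I/O boundary: BED records (0-based, half-open) are converted on
read and write by :mod:`mirpeaks.io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Unicode minus occasionally appears in hand-edited interval notation.
_STRAND_ALIASES = {"+": "+", "-": "-", "−": "-"}

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def normalize_strand(strand: str) -> str:
    """Map a strand symbol (including unicode minus) to ``'+'`` or ``'-'``."""
    try:
        return _STRAND_ALIASES[strand]
    except KeyError:
        raise ValueError(f"invalid strand {strand!r}") from None


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA/RNA string (U treated as T's pair)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class GenomeInterval:
    """A strand-aware, 1-based, closed genomic span."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "strand", normalize_strand(self.strand))
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomeInterval", *, ignore_strand: bool = False) -> bool:
        """True when the two spans share at least one position."""
        if self.chrom != other.chrom:
            return False
        if not ignore_strand and self.strand != other.strand:
            return False
        return self.start <= other.end and other.start <= self.end

    def contains(self, other: "GenomeInterval", *, ignore_strand: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if not ignore_strand and self.strand != other.strand:
            return False
        return self.start <= other.start and other.end <= self.end

    def shifted(self, offset: int) -> "GenomeInterval":
        return GenomeInterval(self.chrom, self.start + offset, self.end + offset, self.strand)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.strand}:{self.start}-{self.end}"


@dataclass(frozen=True, slots=True)
class MappedRead:
    """One aligned small-RNA read; the unit of all counting."""

    sample_id: str
    interval: GenomeInterval
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.interval.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != interval length "
                f"{self.interval.length} for read at {self.interval}"
            )

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True, slots=True)
class MirnaAnnotation:
    """A miRBase-style record: a pre-miRNA hairpin or one of its mature arms."""

    id: str
    kind: str  # "pre_mirna" | "mature"
    interval: GenomeInterval
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("pre_mirna", "mature"):
            raise ValueError(f"unknown annotation kind {self.kind!r}")


@dataclass(frozen=True, slots=True)
class RepeatRecord:
    """One RepeatMasker interval; only ``repeat_class`` is interpreted."""

    interval: GenomeInterval
    repeat_class: str
    repeat_name: str = ""

    def __post_init__(self) -> None:
        if not self.repeat_class:
            raise ValueError("repeat_class must be non-empty")


READ_COLUMNS = ["chrom", "start", "end", "strand", "sample_id"]


def reads_to_frame(reads: Iterable[MappedRead]) -> pd.DataFrame:
    """Tabulate reads into the package's bulk representation.

    Columns: chrom, start, end (1-based closed), strand, sample_id, length.
    """
    reads = list(reads)
    frame = pd.DataFrame(
        {
            "chrom": [r.interval.chrom for r in reads],
            "start": np.asarray([r.interval.start for r in reads], dtype=np.int64),
            "end": np.asarray([r.interval.end for r in reads], dtype=np.int64),
            "strand": [r.interval.strand for r in reads],
            "sample_id": [r.sample_id for r in reads],
        }
    )
    frame["length"] = frame["end"] - frame["start"] + 1
    return frame


def frame_to_reads(frame: pd.DataFrame) -> list[MappedRead]:
    return [
        MappedRead(sample_id=s, interval=GenomeInterval(c, int(a), int(b), st))
        for c, a, b, st, s in zip(
            frame["chrom"], frame["start"], frame["end"], frame["strand"], frame["sample_id"]
        )
    ]


class ReadIndex:
    """Sorted per-(chrom, strand) read coordinates for O(log n) overlap counts.

    A read [s, e] overlaps a query [a, b] iff s <= b and e >= a; the count is
    obtained from two binary searches over independently sorted starts/ends.
    """

    def __init__(self, frame: pd.DataFrame):
        self._groups: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        if len(frame) == 0:
            return
        for (chrom, strand), sub in frame.groupby(["chrom", "strand"], observed=True):
            starts = np.sort(sub["start"].to_numpy(np.int64))
            ends = np.sort(sub["end"].to_numpy(np.int64))
            self._groups[(str(chrom), str(strand))] = (starts, ends)

    @classmethod
    def from_reads(cls, reads: Iterable[MappedRead]) -> "ReadIndex":
        return cls(reads_to_frame(reads))

    def count(self, interval: GenomeInterval, *, ignore_strand: bool = False) -> int:
        """Number of reads overlapping ``interval`` by >= 1 nt."""
        strands = ("+", "-") if ignore_strand else (interval.strand,)
        total = 0
        for strand in strands:
            group = self._groups.get((interval.chrom, strand))
            if group is None:
                continue
            starts, ends = group
            n = len(starts)
            n_start_after = n - int(np.searchsorted(starts, interval.end, side="right"))
            n_end_before = int(np.searchsorted(ends, interval.start, side="left"))
            total += n - n_start_after - n_end_before
        return total

    def count_covering(self, interval: GenomeInterval) -> int:
        """Number of same-strand reads covering *every* position of ``interval``."""
        group = self._groups.get((interval.chrom, interval.strand))
        if group is None:
            return 0
        starts, ends = group
        n = len(starts)
        n_start_late = n - int(np.searchsorted(starts, interval.start, side="right"))
        n_end_early = int(np.searchsorted(ends, interval.end, side="left"))
        return max(n - n_start_late - n_end_early, 0)


def overlap_mask(
    frame: pd.DataFrame,
    intervals: Iterable[GenomeInterval],
    *,
    ignore_strand: bool = False,
) -> np.ndarray:
    """Boolean mask over ``frame`` rows overlapping any of ``intervals``."""
    mask = np.zeros(len(frame), dtype=bool)
    if len(frame) == 0:
        return mask
    chrom = frame["chrom"].to_numpy()
    start = frame["start"].to_numpy(np.int64)
    end = frame["end"].to_numpy(np.int64)
    strand = frame["strand"].to_numpy()
    for iv in intervals:
        hit = (chrom == iv.chrom) & (start <= iv.end) & (end >= iv.start)
        if not ignore_strand:
            hit &= strand == iv.strand
        mask |= hit
    return mask


def chrom_lengths_from_genome(genome: Mapping[str, str]) -> dict[str, int]:
    return {name: len(seq) for name, seq in genome.items()}
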