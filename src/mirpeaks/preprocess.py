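"""Raw-read trimming/clipping and reduction to *informative reads*.

Informative reads are the denominators of every RPM value downstream: mapped
reads of length 18-27 nt that do not touch an RNA-class RepeatMasker repeat
(rRNA, scRNA, snRNA, tRNA, srpRNA, RNA, MARNA). The module also produces
per-library summaries pairing informative-read counts with known-miRNA read
counts, in the style of a sequencing-summary table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    MappedRead,
    MirnaAnnotation,
    RepeatRecord,
    overlap_mask,
    reads_to_frame,
    frame_to_reads,
)

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED_REPEAT_CLASSES = frozenset(
    {"rRNA", "scRNA", "snRNA", "tRNA", "srpRNA", "RNA", "MARNA"}
)


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the trim/clip/informative-read filter chain."""

    min_tail_quality: int = 30
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_len_after_clip: int = 15
    informative_min_len: int = 18
    informative_max_len: int = 27
    excluded_repeat_classes: frozenset[str] = DEFAULT_EXCLUDED_REPEAT_CLASSES

    def __post_init__(self) -> None:
        if not (0 < self.informative_min_len <= self.informative_max_len):
            raise ValueError(
                "require 0 < informative_min_len <= informative_max_len, got "
                f"{self.informative_min_len}..{self.informative_max_len}"
            )


@dataclass(frozen=True)
class LibrarySummary:
    """Per-sample counts of informative and known-miRNA reads."""

    sample_id: str
    n_all_mapped: int
    n_informative: int
    n_known_mirna: int
    portion_known: float | None  # percent, 2 decimals; None when undefined

    @classmethod
    def from_counts(
        cls, sample_id: str, n_all_mapped: int, n_informative: int, n_known_mirna: int
    ) -> "LibrarySummary":
        if n_informative > n_all_mapped:
            raise ValueError("n_informative cannot exceed n_all_mapped")
        portion: float | None
        if n_informative == 0:
            portion = None
        else:
            portion = round_half_up(100.0 * n_known_mirna / n_informative, 2)
        return cls(sample_id, n_all_mapped, n_informative, n_known_mirna, portion)


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal half-up rounding (the convention of printed percentage tables)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def trim_by_quality(
    sequence: str, qualities: Sequence[int], min_tail_quality: int = 30
) -> tuple[str, list[int]]:
    """Remove the maximal 3' suffix in which every base is below the threshold.

    Interior low-quality bases are retained; only the trailing run of
    sub-threshold calls is cut, mirroring tail-quality trimming of raw reads.
    """
    if len(sequence) != len(qualities):
        raise ValueError(
            f"sequence length {len(sequence)} != qualities length {len(qualities)}"
        )
    keep = len(sequence)
    while keep > 0 and qualities[keep - 1] < min_tail_quality:
        keep -= 1
    return sequence[:keep], list(qualities[:keep])


def clip_adapter(
    sequence: str, adapter: str, min_len_after_clip: int = 15, min_prefix: int = 5
) -> str | None:
    """Clip a 3' sequencing adapter by exact match.

    The read is truncated at the leftmost occurrence of the full adapter, or
    of an adapter prefix of length >= ``min_prefix`` that runs to the read's
    end. Reads shorter than ``min_len_after_clip`` after clipping are
    discarded (returns None); reads with no adapter occurrence pass through
    unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    cut = sequence.find(adapter)
    if cut == -1:
        cut = len(sequence)
        # a terminal partial adapter still counts when long enough
        max_tail = min(len(adapter) - 1, len(sequence))
        for tail_len in range(max_tail, min_prefix - 1, -1):
            if sequence.endswith(adapter[:tail_len]):
                cut = len(sequence) - tail_len
                break
    clipped = sequence[:cut]
    if len(clipped) < min_len_after_clip:
        return None
    return clipped


def _informative_mask(
    frame: pd.DataFrame, repeats: Iterable[RepeatRecord], params: FilterParams
) -> np.ndarray:
    lengths = frame["length"].to_numpy(np.int64)
    mask = (lengths >= params.informative_min_len) & (lengths <= params.informative_max_len)
    excluded = [
        r.interval for r in repeats if r.repeat_class in params.excluded_repeat_classes
    ]
    if excluded:
        # repeat masking is positional, so the repeat's strand is ignored
        mask &= ~overlap_mask(frame, excluded, ignore_strand=True)
    return mask


def select_informative_frame(
    frame: pd.DataFrame, repeats: Iterable[RepeatRecord], params: FilterParams | None = None
) -> pd.DataFrame:
    """Vectorised informative-read filter over the bulk read table."""
    params = params or FilterParams()
    return frame[_informative_mask(frame, list(repeats), params)].reset_index(drop=True)


def select_informative(
    reads: Sequence[MappedRead],
    repeats: Iterable[RepeatRecord],
    params: FilterParams | None = None,
) -> list[MappedRead]:
    """Keep reads of informative length not overlapping an excluded repeat.

    A single overlapping position with a repeat of an excluded class (either
    strand) removes the read. Input order is preserved, and the operation is
    idempotent.
    """
    params = params or FilterParams()
    mask = _informative_mask(reads_to_frame(reads), list(repeats), params)
    return [read for read, keep in zip(reads, mask) if keep]


def count_known_mirna_reads(
    frame: pd.DataFrame, known: Iterable[MirnaAnnotation], *, kind: str = "mature"
) -> int:
    """Count reads overlapping any known-miRNA interval on the same strand.

    ``kind`` selects mature arms (default) or pre-miRNA hairpins.
    """
    intervals = [ann.interval for ann in known if ann.kind == kind]
    if not intervals:
        return 0
    return int(overlap_mask(frame, intervals).sum())


def summarize_library(
    all_reads: Sequence[MappedRead] | pd.DataFrame,
    informative: Sequence[MappedRead] | pd.DataFrame,
    known: Iterable[MirnaAnnotation],
    *,
    sample_id: str | None = None,
    known_kind: str = "mature",
) -> LibrarySummary:
    """Build the per-library summary row.

    Known-miRNA reads are counted among *all* mapped reads (strand-aware
    overlap with mature intervals); the printed portion is the known count
    over the informative count, in percent with 2 decimals.
    """
    all_frame = all_reads if isinstance(all_reads, pd.DataFrame) else reads_to_frame(all_reads)
    inf_frame = (
        informative if isinstance(informative, pd.DataFrame) else reads_to_frame(informative)
    )
    if sample_id is None:
        ids = all_frame["sample_id"].unique()
        sample_id = str(ids[0]) if len(ids) == 1 else "pooled"
    n_known = count_known_mirna_reads(all_frame, known, kind=known_kind)
    summary = LibrarySummary.from_counts(
        sample_id=sample_id,
        n_all_mapped=len(all_frame),
        n_informative=len(inf_frame),
        n_known_mirna=n_known,
    )
    if summary.portion_known is None:
        logger.warning("sample %s has no informative reads; portion undefined", sample_id)
    return summary


def summaries_to_frame(summaries: Iterable[LibrarySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "n_all_mapped": s.n_all_mapped,
                "n_informative": s.n_informative,
                "n_known_mirna": s.n_known_mirna,
                "portion_known_pct": s.portion_known,
            }
            for s in summaries
        ]
    )
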