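"""Tier 1 / Tier 2 quality classification of novel pre-miRNA candidates.

Every retained candidate starts in Tier 1 and is demoted to Tier 2 by either
of two scores computed from the reads on its interval (same strand):

* informative-read ratio: n_informative / n_all. Demote when the ratio is
  below 0.5, or when it lies in [0.5, 0.85] and the count difference
  n_all - n_informative exceeds 3. A locus drawing many out-of-length or
  repeat-class reads is unlikely to be a clean Dicer product.
* stem-loop expression: for intervals of 50 nt or longer, split into equal
  halves (genomic-left half gets floor(L/2) nt) and let l and r be the reads
  overlapping each half (a read straddling the internal border counts in
  both) and m the reads overlapping that border. Demote when m/(l+r) exceeds
  0.05 -- real pre-miRNAs have almost no reads across the loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .core import GenomeInterval, MappedRead, ReadIndex
from .discovery import PremiRnaCandidate

logger = logging.getLogger(__name__)

TIER1 = "tier1"
TIER2 = "tier2"
NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class TierParams:
    ratio_hard_floor: float = 0.5
    ratio_soft_ceiling: float = 0.85
    diff_threshold: int = 3
    stemloop_threshold: float = 0.05
    stemloop_min_len: int = 50

    def __post_init__(self) -> None:
        if self.ratio_hard_floor >= self.ratio_soft_ceiling:
            raise ValueError("ratio_hard_floor must be below ratio_soft_ceiling")


@dataclass(frozen=True)
class TierScores:
    n_all: int
    n_informative: int
    informative_ratio: float
    stemloop_l: int | None = None
    stemloop_r: int | None = None
    stemloop_m: int | None = None
    stemloop_score: float | None = None


@dataclass(frozen=True)
class StemloopResult:
    verdict: str  # TIER1 | TIER2 | NOT_APPLICABLE
    l: int | None = None
    r: int | None = None
    m: int | None = None
    score: float | None = None


def informative_ratio_rule(
    n_informative: int, n_all: int, params: TierParams | None = None
) -> str:
    """Classify by the informative/all read ratio.

    Boundary semantics follow the printed prose literally: "less than 0.5"
    is strict, "between 0.5 and 0.85" is closed on both ends, "higher than 3"
    is strict.
    """
    params = params or TierParams()
    if n_all <= 0:
        raise ValueError("n_all must be positive (no reads means no candidate)")
    if not 0 <= n_informative <= n_all:
        raise ValueError("require 0 <= n_informative <= n_all")
    ratio = n_informative / n_all
    if ratio < params.ratio_hard_floor:
        return TIER2
    if (
        params.ratio_hard_floor <= ratio <= params.ratio_soft_ceiling
        and n_all - n_informative > params.diff_threshold
    ):
        return TIER2
    return TIER1


def stemloop_rule(
    reads: Sequence[MappedRead] | ReadIndex,
    interval: GenomeInterval,
    params: TierParams | None = None,
) -> StemloopResult:
    """Classify by loop expression m/(l+r) for intervals >= 50 nt.

    ``reads`` should be the all-mapped-read set; only same-strand reads are
    counted. The internal border lies between the equal halves; a read
    covering both border positions counts in l, r and m.
    """
    params = params or TierParams()
    if interval.length < params.stemloop_min_len:
        return StemloopResult(NOT_APPLICABLE)
    index = reads if isinstance(reads, ReadIndex) else ReadIndex.from_reads(reads)
    half = interval.length // 2
    mid = interval.start + half - 1  # last position of the genomic-left half
    left = GenomeInterval(interval.chrom, interval.start, mid, interval.strand)
    right = GenomeInterval(interval.chrom, mid + 1, interval.end, interval.strand)
    border = GenomeInterval(interval.chrom, mid, mid + 1, interval.strand)
    l = index.count(left)
    r = index.count(right)
    m = index.count_covering(border)
    if l + r == 0:
        logger.warning(
            "stem-loop score undefined at %s (no shoulder reads); treating as 0",
            interval,
        )
        return StemloopResult(TIER1, l, r, m, 0.0)
    score = m / (l + r)
    verdict = TIER2 if score > params.stemloop_threshold else TIER1
    return StemloopResult(verdict, l, r, m, score)


def assign_tier(
    candidate: PremiRnaCandidate,
    all_reads: Sequence[MappedRead] | ReadIndex,
    informative_reads: Sequence[MappedRead] | ReadIndex,
    params: TierParams | None = None,
) -> PremiRnaCandidate:
    """Attach tier scores and the Tier 1 / Tier 2 label to a candidate.

    The candidate starts in Tier 1 and is demoted if either rule demotes it;
    both scores are stored on the candidate.
    """
    params = params or TierParams()
    all_index = (
        all_reads if isinstance(all_reads, ReadIndex) else ReadIndex.from_reads(all_reads)
    )
    inf_index = (
        informative_reads
        if isinstance(informative_reads, ReadIndex)
        else ReadIndex.from_reads(informative_reads)
    )
    n_all = all_index.count(candidate.interval)
    n_informative = inf_index.count(candidate.interval)
    ratio_verdict = informative_ratio_rule(n_informative, n_all, params)
    stemloop = stemloop_rule(all_index, candidate.interval, params)
    candidate.tier = (
        TIER2 if TIER2 in (ratio_verdict, stemloop.verdict) else TIER1
    )
    candidate.tier_scores = TierScores(
        n_all=n_all,
        n_informative=n_informative,
        informative_ratio=n_informative / n_all,
        stemloop_l=stemloop.l,
        stemloop_r=stemloop.r,
        stemloop_m=stemloop.m,
        stemloop_score=stemloop.score,
    )
    return candidate
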