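"""Extremum fold-change differential expression between PSC and EF groups.

With only two embryonic-fibroblast libraries, p-values carry little weight,
so the classifier relies on strong fold-change conditions instead. A feature
is called up in PSCs when the PSC/EF group-mean RPM ratio is at least 3 and
the *minimum* PSC RPM is at least ``extremum_factor`` (2, or 10 in a stricter
parallel analysis) times the *maximum* EF RPM. Up-in-EF calls are symmetric
and additionally require at least three raw mapped reads in every EF sample.
Comparing the extrema of the two groups makes a call robust to any single
outlier library, which is the point of the method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

from .expression import ExpressionMatrix

PSC = "PSC"
EF = "EF"

UP_IN_PSC = "up_in_psc"
UP_IN_EF = "up_in_ef"
NOT_SIGNIFICANT = "not_significant"


@dataclass(frozen=True)
class DiffExpParams:
    avg_ratio_min: float = 3.0
    extremum_factor: float = 2.0
    min_reads_per_ef_sample: int = 3

    def __post_init__(self) -> None:
        if min(self.avg_ratio_min, self.extremum_factor, self.min_reads_per_ef_sample) < 1:
            raise ValueError("all differential-expression parameters must be >= 1")


@dataclass(frozen=True)
class DiffExpCall:
    feature_id: str
    direction: str
    psc_mean: float
    ef_mean: float
    psc_min: float
    psc_max: float
    ef_min: float
    ef_max: float
    avg_ratio: float


def _avg_ratio(mean_a: float, mean_b: float) -> float:
    hi, lo = max(mean_a, mean_b), min(mean_a, mean_b)
    if lo == 0:
        return math.inf if hi > 0 else 1.0
    return hi / lo


def extremum_fold_change_classify(
    matrix: ExpressionMatrix,
    groups: Mapping[str, str],
    params: DiffExpParams | None = None,
) -> list[DiffExpCall]:
    """Classify every feature as up_in_psc, up_in_ef or not_significant.

    ``groups`` maps each sample id of the matrix to "PSC" or "EF"; both
    groups must be non-empty. Zero handling: the extremum condition
    min >= factor * max is only accepted when the minimum itself is positive,
    so all-zero features are never called. The >= 3 reads guard uses raw
    counts, not RPM, and applies only to up-in-EF calls.
    """
    params = params or DiffExpParams()
    unknown = {g for g in groups.values()} - {PSC, EF}
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    psc_samples = [s for s in matrix.samples if groups.get(s) == PSC]
    ef_samples = [s for s in matrix.samples if groups.get(s) == EF]
    if not psc_samples or not ef_samples:
        raise ValueError("need at least one sample in each of PSC and EF")

    calls: list[DiffExpCall] = []
    for feature in matrix.features:
        rpm = matrix.rpm.loc[feature.id]
        raw = matrix.raw.loc[feature.id]
        psc = rpm[psc_samples].to_numpy(float)
        ef = rpm[ef_samples].to_numpy(float)
        psc_mean, ef_mean = float(psc.mean()), float(ef.mean())
        psc_min, psc_max = float(psc.min()), float(psc.max())
        ef_min, ef_max = float(ef.min()), float(ef.max())
        ratio = _avg_ratio(psc_mean, ef_mean)

        direction = NOT_SIGNIFICANT
        if (
            psc_mean > ef_mean
            and ratio >= params.avg_ratio_min
            and psc_min > 0
            and psc_min >= params.extremum_factor * ef_max
        ):
            direction = UP_IN_PSC
        elif (
            ef_mean > psc_mean
            and ratio >= params.avg_ratio_min
            and ef_min > 0
            and ef_min >= params.extremum_factor * psc_max
            and all(int(raw[s]) >= params.min_reads_per_ef_sample for s in ef_samples)
        ):
            direction = UP_IN_EF

        calls.append(
            DiffExpCall(
                feature_id=feature.id,
                direction=direction,
                psc_mean=psc_mean,
                ef_mean=ef_mean,
                psc_min=psc_min,
                psc_max=psc_max,
                ef_min=ef_min,
                ef_max=ef_max,
                avg_ratio=ratio,
            )
        )
    return calls


class DirectionCounts(NamedTuple):
    n_up_psc: int
    n_up_ef: int
    n_not_significant: int


def count_directions(calls: Sequence[DiffExpCall]) -> DirectionCounts:
    """Tally calls by direction; the three counts sum to the feature count."""
    n_psc = sum(1 for c in calls if c.direction == UP_IN_PSC)
    n_ef = sum(1 for c in calls if c.direction == UP_IN_EF)
    return DirectionCounts(n_psc, n_ef, len(calls) - n_psc - n_ef)


def calls_to_frame(calls: Sequence[DiffExpCall]):
    import pandas as pd

    return pd.DataFrame([c.__dict__ for c in calls])
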