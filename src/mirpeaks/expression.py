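"""Digital gene expression of known and novel miRNAs.

Counting is strand-aware with a border rule: any read overlapping a feature
interval by at least one nucleotide contributes exactly 1 to that feature's
raw count. Raw counts X_i^j are normalised to reads-per-million as

    x_i^j = X_i^j * 1e6 / informative_reads_i

where the denominator is the sample's informative-read total even when the
counts themselves come from all mapped reads. Long novel pre-miRNA intervals
are split into equal genomic halves to mimic the mature products of the 5'
and 3' hairpin shoulders, and candidates whose sequences recur at
overlapping genomic placements have their expression pooled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomeInterval, MappedRead, ReadIndex, reads_to_frame
from .discovery import PremiRnaCandidate, find_occurrences


@dataclass(frozen=True)
class Feature:
    """A quantified genomic feature (mature miRNA, candidate, or shoulder)."""

    id: str
    interval: GenomeInterval


@dataclass(frozen=True)
class ShoulderPair:
    """Equal-half split of a long pre-miRNA interval into 5p/3p shoulders.

    The genomic-left half has floor(L/2) nt; on the + strand it is the 5p
    shoulder, on the - strand the 3p shoulder.
    """

    parent: GenomeInterval
    left: GenomeInterval
    right: GenomeInterval

    @property
    def left_label(self) -> str:
        return "5p" if self.parent.strand == "+" else "3p"

    @property
    def right_label(self) -> str:
        return "3p" if self.parent.strand == "+" else "5p"


def split_shoulders(parent: GenomeInterval, threshold: int = 50) -> ShoulderPair | None:
    """Split intervals longer than ``threshold`` nt into two abutting halves.

    Returns None for intervals of ``threshold`` nt or shorter. The split
    point gives the genomic-left half floor(L/2) positions.
    """
    if parent.length <= threshold:
        return None
    half = parent.length // 2
    left = GenomeInterval(parent.chrom, parent.start, parent.start + half - 1, parent.strand)
    right = GenomeInterval(parent.chrom, parent.start + half, parent.end, parent.strand)
    return ShoulderPair(parent=parent, left=left, right=right)


def count_interval_reads(
    reads: Sequence[MappedRead] | ReadIndex, interval: GenomeInterval
) -> int:
    """Strand-aware overlap count with the border rule (>=1 nt => counts 1)."""
    index = reads if isinstance(reads, ReadIndex) else ReadIndex.from_reads(reads)
    return index.count(interval)


def rpm_normalize(raw: float, informative_total: int) -> float:
    """Reads-per-million scaling of a raw count by an informative total."""
    if informative_total <= 0:
        raise ValueError("informative_total must be positive")
    return raw * 1e6 / informative_total


@dataclass
class ExpressionMatrix:
    """Feature x sample raw counts with RPM values and sample totals."""

    features: list[Feature]
    informative_totals: dict[str, int]
    raw: pd.DataFrame  # index: feature ids; columns: sample ids; int64
    rpm: pd.DataFrame
    counting_mode: str = "all_reads"

    @property
    def samples(self) -> list[str]:
        return list(self.raw.columns)

    def feature_by_id(self, feature_id: str) -> Feature:
        for feature in self.features:
            if feature.id == feature_id:
                return feature
        raise KeyError(feature_id)

    def recompute_rpm(self) -> pd.DataFrame:
        """Re-derive RPM from raw counts and totals (used for exactness checks)."""
        totals = np.array([self.informative_totals[s] for s in self.raw.columns], dtype=float)
        return self.raw.astype(float) * 1e6 / totals

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for feature in self.features:
            row: dict[str, object] = {
                "feature_id": feature.id,
                "chrom": feature.interval.chrom,
                "start": feature.interval.start,
                "end": feature.interval.end,
                "strand": feature.interval.strand,
            }
            for sample in self.samples:
                row[f"raw_{sample}"] = int(self.raw.at[feature.id, sample])
                row[f"rpm_{sample}"] = float(self.rpm.at[feature.id, sample])
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path, informative_totals: Mapping[str, int], counting_mode: str = "all_reads"
    ) -> "ExpressionMatrix":
        frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        samples = [c[4:] for c in frame.columns if c.startswith("raw_")]
        features = [
            Feature(
                str(r.feature_id),
                GenomeInterval(str(r.chrom), int(r.start), int(r.end), str(r.strand)),
            )
            for r in frame.itertuples(index=False)
        ]
        ids = [f.id for f in features]
        raw = pd.DataFrame(
            {s: frame[f"raw_{s}"].to_numpy(np.int64) for s in samples}, index=ids
        )
        rpm = pd.DataFrame(
            {s: frame[f"rpm_{s}"].to_numpy(float) for s in samples}, index=ids
        )
        return cls(features, dict(informative_totals), raw, rpm, counting_mode)


def build_expression_matrix(
    features: Sequence[Feature],
    reads_by_sample: Mapping[str, Sequence[MappedRead] | pd.DataFrame | ReadIndex],
    informative_totals: Mapping[str, int],
    counting_mode: str = "all_reads",
) -> ExpressionMatrix:
    """Count every feature in every sample and normalise to RPM.

    ``counting_mode`` records whether the supplied reads are all mapped reads
    (default) or the informative subset; the RPM denominator is the per-sample
    informative total in both modes.
    """
    ids = [f.id for f in features]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate feature ids: {dupes}")
    samples = list(reads_by_sample)
    raw = pd.DataFrame(0, index=ids, columns=samples, dtype=np.int64)
    for sample, reads in reads_by_sample.items():
        if isinstance(reads, ReadIndex):
            index = reads
        elif isinstance(reads, pd.DataFrame):
            index = ReadIndex(reads)
        else:
            index = ReadIndex(reads_to_frame(reads))
        for feature in features:
            raw.at[feature.id, sample] = index.count(feature.interval)
    totals = {s: int(informative_totals[s]) for s in samples}
    rpm = raw.astype(float) * 1e6 / np.array([totals[s] for s in samples], dtype=float)
    return ExpressionMatrix(
        features=list(features),
        informative_totals=totals,
        raw=raw,
        rpm=rpm,
        counting_mode=counting_mode,
    )


def candidate_features(
    candidates: Sequence[PremiRnaCandidate], split_threshold: int = 50
) -> list[Feature]:
    """Features for candidate quantification, shoulder-splitting long loci.

    Intervals longer than ``split_threshold`` yield two features suffixed by
    their 5p/3p shoulder labels; shorter loci are quantified whole.
    """
    features: list[Feature] = []
    for cand in candidates:
        pair = split_shoulders(cand.interval, split_threshold)
        if pair is None:
            features.append(Feature(cand.id, cand.interval))
        else:
            features.append(Feature(f"{cand.id}-{pair.left_label}", pair.left))
            features.append(Feature(f"{cand.id}-{pair.right_label}", pair.right))
    return features


def merge_duplicate_expression(
    candidates: Sequence[PremiRnaCandidate],
    genome: Mapping[str, str],
    matrix: ExpressionMatrix,
) -> ExpressionMatrix:
    """Pool expression of candidates that are genomic duplicates.

    Each candidate's exact-match occurrence intervals (both strands) are
    located genome-wide; candidates whose occurrence sets contain overlapping
    intervals form one pooled feature whose raw counts are the member sums,
    with RPM recomputed. The merged feature id concatenates member ids in
    lexicographic order; its interval is the first member's (a representative
    placement). ``matrix`` must be a candidate-level (unsplit) matrix.
    """
    ids = [c.id for c in candidates]
    occurrence_sets = {c.id: find_occurrences(c.sequence, genome) for c in candidates}

    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if find(a) == find(b):
                continue
            hits_a, hits_b = occurrence_sets[a], occurrence_sets[b]
            if any(
                ia.overlaps(ib, ignore_strand=True) for ia in hits_a for ib in hits_b
            ):
                union(a, b)

    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)

    by_id = {c.id: c for c in candidates}
    features: list[Feature] = []
    raw_rows = {}
    for members in groups.values():
        members = sorted(members)
        merged_id = "+".join(members)
        features.append(Feature(merged_id, by_id[members[0]].interval))
        raw_rows[merged_id] = matrix.raw.loc[members].sum(axis=0)
    raw = pd.DataFrame(raw_rows).T.astype(np.int64)
    raw = raw.loc[[f.id for f in features], matrix.samples]
    totals = dict(matrix.informative_totals)
    rpm = raw.astype(float) * 1e6 / np.array(
        [totals[s] for s in matrix.samples], dtype=float
    )
    return ExpressionMatrix(
        features=features,
        informative_totals=totals,
        raw=raw,
        rpm=rpm,
        counting_mode=matrix.counting_mode,
    )
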