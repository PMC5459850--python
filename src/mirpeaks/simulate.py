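"""Synthetic small-RNA cohort generator with a machine-readable truth table.

The generator emulates the data structure the analysis assumes: a toy genome
with planted known and novel pre-miRNA hairpins (arm + loop +
reverse-complemented arm, so the hairpin test holds by construction),
RNA-class repeat regions, and eleven mapped-read libraries in two groups
(nine pluripotent stem cell samples, two embryonic fibroblast samples).
Mature-length reads pile up on the two hairpin arms with a small end wobble,
producing the double-peak coverage signature; planted fold changes drive
group-specific expression, and dedicated loci exercise the tier demotion
rules, duplicate-expression merging and the genome-occurrence filter. Every
output is a deterministic function of the seed.

Reads are emitted post-alignment (BED-style records); a small FASTQ emitter
with adapter and low-quality tails exists solely to exercise the trim/clip
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    GenomeInterval,
    MirnaAnnotation,
    RepeatRecord,
    reverse_complement,
)
from . import io as mio

_BASES = np.array(list("ACGT"))

#: informative-length distribution for noise reads: discrete 18-27, mode 22
_INF_LENGTHS = np.arange(18, 28)
_INF_LENGTH_WEIGHTS = np.array([1, 2, 5, 9, 12, 9, 6, 4, 2, 1], dtype=float)
_INF_LENGTH_WEIGHTS /= _INF_LENGTH_WEIGHTS.sum()

#: out-of-range lengths: short degradation products and long fragments
_OUT_LENGTHS = np.array([14, 15, 16, 17, 28, 30, 32, 34])

_REPEAT_CLASSES = ["rRNA", "tRNA", "snRNA", "scRNA", "srpRNA", "RNA", "MARNA"]


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    group: str  # "PSC" | "EF"
    depth: int = 40_000  # target informative-read count


def default_samples() -> tuple[SampleSpec, ...]:
    """Nine PSC libraries (seven iPSC + two ESC) and two EF libraries."""
    ids = [f"iPSC_{i}" for i in range(1, 8)] + ["ESC_1", "ESC_2", "EF_1", "EF_2"]
    return tuple(
        SampleSpec(s, "EF" if s.startswith("EF") else "PSC") for s in ids
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the generator."""

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 200_000
    n_known_mirnas: int = 30
    n_novel_mirnas: int = 20
    n_repeat_regions: int = 40
    repeat_length_range: tuple[int, int] = (80, 300)
    # Hairpin geometry. The sub-ranges keep the observed double-peak signal
    # (peak length, valley width) inside the caller's default windows even at
    # the +-2 nt read-end wobble extremes.
    arm_length_range: tuple[int, int] = (22, 25)
    loop_length_range: tuple[int, int] = (12, 26)
    flank_length: int = 12
    samples: tuple[SampleSpec, ...] = field(default_factory=default_samples)
    # Expression model: per-arm expected reads per sample, log-uniform.
    known_weight_range: tuple[float, float] = (20.0, 3000.0)
    novel_weight_range: tuple[float, float] = (30.0, 1000.0)
    de_weight_range: tuple[float, float] = (100.0, 1000.0)
    de_factors: tuple[float, float] = (6.0, 20.0)
    n_de_per_cell: int = 3  # loci per (direction, factor) combination
    family_copies: int = 2
    overcopy_placements: int = 16
    overcopy_weight: float = 800.0
    n_dirty_straddle: int = 1
    n_dirty_oversize: int = 1
    straddle_rate: float = 0.1    # loop-straddling reads per locus read
    oversize_rate: float = 1.5    # oversized arm reads per locus read
    # Noise classes, as fractions of the per-sample depth.
    background_fraction: float = 0.005
    repeat_read_fraction: float = 0.02
    outlength_fraction: float = 0.02
    wobble_probs: tuple[float, ...] = (0.05, 0.15, 0.6, 0.15, 0.05)  # offsets -2..+2
    min_separation: int = 150
    noise_buffer: int = 100

    def __post_init__(self) -> None:
        if self.arm_length_range[0] > self.arm_length_range[1]:
            raise ValueError("bad arm_length_range")
        if self.loop_length_range[0] > self.loop_length_range[1]:
            raise ValueError("bad loop_length_range")
        n_special = (
            4 * self.n_de_per_cell
            + self.family_copies
            + 1  # overcopied locus
            + self.n_dirty_straddle
            + self.n_dirty_oversize
        )
        if self.n_novel_mirnas and self.n_novel_mirnas < n_special:
            raise ValueError(
                f"n_novel_mirnas={self.n_novel_mirnas} cannot fit the "
                f"{n_special} special loci (DE, family, overcopy, dirty)"
            )

    def groups(self) -> dict[str, str]:
        return {s.sample_id: s.group for s in self.samples}


@dataclass
class LocusTruth:
    """Everything needed to score the pipeline against one planted locus."""

    locus_id: str
    kind: str                      # "known" | "novel"
    interval: GenomeInterval       # pre-miRNA span (arm+loop+arm)
    arm5: GenomeInterval           # genomic-left arm
    arm3: GenomeInterval           # genomic-right arm
    sequence: str
    family_id: str
    copy_number: int
    weight_psc: float              # expected reads per arm per PSC sample
    weight_ef: float
    expected_rpm_psc: float = 0.0  # interval-level, filled after depth scaling
    expected_rpm_ef: float = 0.0
    de_direction: str = "not_significant"  # truth label; "excluded" for overcopy
    de_factor: float = 1.0
    expected_tier: str | None = None       # novel loci only
    dirt: str = "none"                     # none | straddle | oversize
    expect_discovery: bool = True
    placements: list[GenomeInterval] = field(default_factory=list)  # all copies


@dataclass
class SimTruth:
    loci: list[LocusTruth]
    expected_totals: dict[str, float]  # per-sample expected informative totals

    def novel(self) -> list[LocusTruth]:
        return [l for l in self.loci if l.kind == "novel"]

    def known(self) -> list[LocusTruth]:
        return [l for l in self.loci if l.kind == "known"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for l in self.loci:
            rows.append(
                {
                    "locus_id": l.locus_id,
                    "kind": l.kind,
                    "chrom": l.interval.chrom,
                    "start": l.interval.start,
                    "end": l.interval.end,
                    "strand": l.interval.strand,
                    "family_id": l.family_id,
                    "copy_number": l.copy_number,
                    "weight_psc": l.weight_psc,
                    "weight_ef": l.weight_ef,
                    "expected_rpm_psc": l.expected_rpm_psc,
                    "expected_rpm_ef": l.expected_rpm_ef,
                    "de_direction": l.de_direction,
                    "de_factor": l.de_factor,
                    "expected_tier": l.expected_tier or "",
                    "dirt": l.dirt,
                    "expect_discovery": l.expect_discovery,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedData:
    config: SimConfig
    genome: dict[str, str]
    known: list[MirnaAnnotation]
    repeats: list[RepeatRecord]
    truth: SimTruth


# ---------------------------------------------------------------------------
# genome construction


class _Packer:
    """Random non-overlapping placement with a separation margin."""

    def __init__(self, rng: np.random.Generator, chrom_names: list[str], length: int,
                 min_separation: int):
        self.rng = rng
        self.chrom_names = chrom_names
        self.length = length
        self.min_separation = min_separation
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def place(self, footprint: int) -> tuple[str, int]:
        for _ in range(2000):
            chrom = self.chrom_names[int(self.rng.integers(len(self.chrom_names)))]
            start = int(self.rng.integers(1 + self.min_separation,
                                          self.length - footprint - self.min_separation))
            end = start + footprint - 1
            margin = self.min_separation
            if all(
                end + margin < s or start - margin > e
                for s, e in self.occupied[chrom]
            ):
                self.occupied[chrom].append((start, end))
                return chrom, start
        raise RuntimeError(
            "infeasible packing: too many planted elements for the genome size"
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _hairpin_seq(rng: np.random.Generator, arm_len: int, loop_len: int) -> str:
    arm = _random_seq(rng, arm_len)
    loop = _random_seq(rng, loop_len)
    return arm + loop + reverse_complement(arm)


def simulate_genome(config: SimConfig | None = None) -> SimulatedData:
    """Build the toy genome, annotations, repeats and the truth table.

    Deterministic under ``config.seed``: the same configuration always yields
    byte-identical FASTA/GFF3/TSV outputs.
    """
    config = config or SimConfig()
    rng = np.random.default_rng([config.seed, 0])
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_arrays = {
        c: rng.integers(0, 4, size=config.chromosome_length) for c in chrom_names
    }
    packer = _Packer(rng, chrom_names, config.chromosome_length, config.min_separation)

    def embed(chrom: str, start: int, seq: str) -> None:
        idx = np.searchsorted(_BASES, np.array(list(seq)))
        chrom_arrays[chrom][start - 1 : start - 1 + len(seq)] = idx

    def log_uniform(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    loci: list[LocusTruth] = []

    def plant_locus(
        locus_id: str,
        kind: str,
        *,
        n_copies: int = 1,
        family_id: str | None = None,
        with_flanks: bool = False,
    ) -> LocusTruth:
        arm_len = int(rng.integers(config.arm_length_range[0], config.arm_length_range[1] + 1))
        loop_len = int(rng.integers(config.loop_length_range[0], config.loop_length_range[1] + 1))
        pre = _hairpin_seq(rng, arm_len, loop_len)
        flank5 = _random_seq(rng, config.flank_length) if with_flanks else ""
        flank3 = _random_seq(rng, config.flank_length) if with_flanks else ""
        strand = "+" if rng.random() < 0.5 else "-"
        placements: list[GenomeInterval] = []
        for _ in range(n_copies):
            footprint = len(flank5) + len(pre) + len(flank3)
            chrom, start = packer.place(footprint)
            embed(chrom, start, flank5 + pre + flank3)
            pre_start = start + len(flank5)
            placements.append(
                GenomeInterval(chrom, pre_start, pre_start + len(pre) - 1, strand)
            )
        primary = placements[0]
        arm5 = GenomeInterval(primary.chrom, primary.start, primary.start + arm_len - 1, strand)
        arm3 = GenomeInterval(primary.chrom, primary.end - arm_len + 1, primary.end, strand)
        locus = LocusTruth(
            locus_id=locus_id,
            kind=kind,
            interval=primary,
            arm5=arm5,
            arm3=arm3,
            sequence=pre,
            family_id=family_id or locus_id,
            copy_number=n_copies,
            weight_psc=0.0,
            weight_ef=0.0,
            placements=placements,
        )
        loci.append(locus)
        return locus

    # --- known miRNAs: expressed equally in both groups
    for k in range(config.n_known_mirnas):
        locus = plant_locus(f"sim-mir-{k + 1}", "known")
        w = log_uniform(*config.known_weight_range)
        locus.weight_psc = locus.weight_ef = w

    # --- novel loci
    n_novel = config.n_novel_mirnas
    if n_novel:
        novel_count = 0

        def next_id() -> str:
            nonlocal novel_count
            novel_count += 1
            return f"sim-novel-{novel_count}"

        # differentially expressed loci
        for direction in ("up_in_psc", "up_in_ef"):
            for factor in config.de_factors:
                for _ in range(config.n_de_per_cell):
                    locus = plant_locus(next_id(), "novel")
                    w = log_uniform(*config.de_weight_range)
                    if direction == "up_in_psc":
                        locus.weight_psc, locus.weight_ef = w, w / factor
                    else:
                        locus.weight_ef, locus.weight_psc = w, w / factor
                    locus.de_direction = direction
                    locus.de_factor = factor
                    locus.expected_tier = "tier1"

        # a null family of identical copies (duplicate-expression merging)
        family_weight = log_uniform(*config.novel_weight_range)
        family = plant_locus(
            next_id(), "novel", n_copies=config.family_copies,
            family_id="sim-family-1", with_flanks=True,
        )
        family.weight_psc = family.weight_ef = family_weight
        family.expected_tier = "tier1"

        # an over-copied locus: expressed once, sequence planted >15 times
        overcopy = plant_locus(
            next_id(), "novel", n_copies=config.overcopy_placements,
            family_id="sim-overcopy-1", with_flanks=True,
        )
        overcopy.weight_psc = overcopy.weight_ef = config.overcopy_weight
        overcopy.de_direction = "excluded"
        overcopy.expect_discovery = False
        overcopy.expected_tier = None

        # dirty loci exercising the two tier-demotion rules
        for _ in range(config.n_dirty_straddle):
            locus = plant_locus(next_id(), "novel")
            locus.weight_psc = locus.weight_ef = log_uniform(*config.novel_weight_range)
            locus.dirt = "straddle"
            locus.expected_tier = "tier2"
        for _ in range(config.n_dirty_oversize):
            locus = plant_locus(next_id(), "novel")
            locus.weight_psc = locus.weight_ef = log_uniform(*config.novel_weight_range)
            locus.dirt = "oversize"
            locus.expected_tier = "tier2"

        # plain null loci
        while novel_count < n_novel:
            locus = plant_locus(next_id(), "novel")
            locus.weight_psc = locus.weight_ef = log_uniform(*config.novel_weight_range)
            locus.expected_tier = "tier1"

    # --- repeats
    repeats: list[RepeatRecord] = []
    for r in range(config.n_repeat_regions):
        length = int(rng.integers(*config.repeat_length_range))
        chrom, start = packer.place(length)
        strand = "+" if rng.random() < 0.5 else "-"
        repeat_class = _REPEAT_CLASSES[r % len(_REPEAT_CLASSES)]
        repeats.append(
            RepeatRecord(
                interval=GenomeInterval(chrom, start, start + length - 1, strand),
                repeat_class=repeat_class,
                repeat_name=f"{repeat_class}-sim-{r + 1}",
            )
        )

    # --- depth scaling and expected RPM truth values
    psc_arm_sum = sum(2 * l.weight_psc for l in loci)
    ef_arm_sum = sum(2 * l.weight_ef for l in loci)
    informative_share = 1.0 - config.background_fraction
    expected_totals: dict[str, float] = {}
    for spec in config.samples:
        arm_sum = psc_arm_sum if spec.group == "PSC" else ef_arm_sum
        planted = spec.depth * informative_share * (arm_sum / psc_arm_sum)
        expected_totals[spec.sample_id] = planted + spec.depth * config.background_fraction
    depth_by_group: dict[str, float] = {}
    for g in ("PSC", "EF"):
        members = [s.depth for s in config.samples if s.group == g]
        depth_by_group[g] = float(np.mean(members)) if members else 0.0
    scale = informative_share / psc_arm_sum  # expected reads per weight unit, per depth
    for locus in loci:
        count_psc = 2 * locus.weight_psc * scale * depth_by_group["PSC"]
        count_ef = 2 * locus.weight_ef * scale * depth_by_group["EF"]
        psc_total = np.mean(
            [expected_totals[s.sample_id] for s in config.samples if s.group == "PSC"]
        )
        ef_total = np.mean(
            [expected_totals[s.sample_id] for s in config.samples if s.group == "EF"]
        ) if any(s.group == "EF" for s in config.samples) else np.nan
        locus.expected_rpm_psc = count_psc * 1e6 / psc_total
        locus.expected_rpm_ef = (
            count_ef * 1e6 / ef_total if np.isfinite(ef_total) else 0.0
        )

    # --- annotation records for known loci
    known: list[MirnaAnnotation] = []
    for locus in loci:
        if locus.kind != "known":
            continue
        known.append(MirnaAnnotation(locus.locus_id, "pre_mirna", locus.interval))
        left_label = "5p" if locus.interval.strand == "+" else "3p"
        right_label = "3p" if locus.interval.strand == "+" else "5p"
        known.append(
            MirnaAnnotation(
                f"{locus.locus_id}-{left_label}", "mature", locus.arm5, locus.locus_id
            )
        )
        known.append(
            MirnaAnnotation(
                f"{locus.locus_id}-{right_label}", "mature", locus.arm3, locus.locus_id
            )
        )

    genome = {c: "".join(_BASES[arr]) for c, arr in chrom_arrays.items()}
    return SimulatedData(
        config=config,
        genome=genome,
        known=known,
        repeats=repeats,
        truth=SimTruth(loci=loci, expected_totals=expected_totals),
    )


# ---------------------------------------------------------------------------
# read simulation


def _allowed_segments(
    sim: SimulatedData, max_read_len: int
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome complement of the planted-locus buffer zones.

    Returns (seg_starts, seg_ends, cumulative_weights) per chromosome for
    weighted uniform sampling of noise read positions.
    """
    config = sim.config
    buffer = config.noise_buffer
    zones: dict[str, list[tuple[int, int]]] = {c: [] for c in sim.genome}
    for locus in sim.truth.loci:
        for placement in locus.placements:
            zones[placement.chrom].append(
                (placement.start - buffer, placement.end + buffer)
            )
    out = {}
    for chrom, seq in sim.genome.items():
        merged: list[tuple[int, int]] = []
        for s, e in sorted(zones[chrom]):
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        seg_starts, seg_ends = [], []
        cursor = 1
        for s, e in merged + [(len(seq) + 1, len(seq) + 1)]:
            if s - 1 - max_read_len >= cursor:
                seg_starts.append(cursor)
                seg_ends.append(s - 1 - max_read_len)  # start positions only
            cursor = max(cursor, e + 1)
        starts = np.array(seg_starts, dtype=np.int64)
        ends = np.array(seg_ends, dtype=np.int64)
        weights = (ends - starts + 1).astype(float)
        out[chrom] = (starts, ends, np.cumsum(weights) / weights.sum())
    return out


def _sample_noise_positions(
    rng: np.random.Generator,
    segments: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n read start positions uniformly over the allowed segments."""
    chroms = np.array(sorted(segments))
    sizes = np.array(
        [float(segments[c][1][-1] - segments[c][0][0]) if len(segments[c][0]) else 0.0
         for c in chroms]
    )
    probs = sizes / sizes.sum()
    chosen = rng.choice(len(chroms), size=n, p=probs)
    starts = np.empty(n, dtype=np.int64)
    for i, c_idx in enumerate(chosen):
        seg_starts, seg_ends, cum = segments[chroms[c_idx]]
        seg = int(np.searchsorted(cum, rng.random()))
        starts[i] = int(rng.integers(seg_starts[seg], seg_ends[seg] + 1))
    return chroms[chosen], starts


def simulate_reads(sim: SimulatedData) -> pd.DataFrame:
    """Generate mapped reads for every sample of the configured cohort.

    Per locus arm and sample, the read count is Poisson around the planted
    expectation; read ends wobble by up to +-2 nt with lengths clamped to the
    18-27 nt mature range. Multi-copy loci scatter each read onto one random
    placement. Noise classes: repeat-region reads, out-of-length reads, and
    uniform background reads (the latter two placed outside a buffer around
    planted loci). Deterministic under the configuration seed.
    """
    config = sim.config
    rng = np.random.default_rng([config.seed, 1])
    offsets = np.arange(-2, 3)
    wobble = np.asarray(config.wobble_probs, dtype=float)
    wobble = wobble / wobble.sum()

    psc_arm_sum = sum(2 * l.weight_psc for l in sim.truth.loci)
    informative_share = 1.0 - config.background_fraction

    rows_chrom: list[np.ndarray] = []
    rows_start: list[np.ndarray] = []
    rows_end: list[np.ndarray] = []
    rows_strand: list[np.ndarray] = []
    rows_sample: list[np.ndarray] = []

    def emit(chrom, start, end, strand, sample_id, n):
        rows_chrom.append(np.asarray(chrom, dtype=object))
        rows_start.append(np.asarray(start, dtype=np.int64))
        rows_end.append(np.asarray(end, dtype=np.int64))
        rows_strand.append(np.asarray(strand, dtype=object))
        rows_sample.append(np.full(n, sample_id, dtype=object))

    segments = _allowed_segments(sim, max_read_len=40)
    for spec in config.samples:
        scale = informative_share * spec.depth / psc_arm_sum
        for locus in sim.truth.loci:
            weight = locus.weight_psc if spec.group == "PSC" else locus.weight_ef
            lam = weight * scale
            if lam <= 0:
                continue
            arm_len = locus.arm5.length
            for arm_pos in (0, 1):  # 0: genomic-left arm, 1: genomic-right arm
                n = int(rng.poisson(lam))
                if n == 0:
                    continue
                copy_idx = (
                    rng.integers(0, locus.copy_number, size=n)
                    if locus.copy_number > 1
                    else np.zeros(n, dtype=np.int64)
                )
                placement_starts = np.array(
                    [p.start for p in locus.placements], dtype=np.int64
                )
                pre_len = locus.interval.length
                if arm_pos == 0:
                    arm_start = placement_starts[copy_idx]
                    arm_end = arm_start + arm_len - 1
                else:
                    arm_end = placement_starts[copy_idx] + pre_len - 1
                    arm_start = arm_end - arm_len + 1
                w1 = rng.choice(offsets, size=n, p=wobble)
                w2 = rng.choice(offsets, size=n, p=wobble)
                start = arm_start + w1
                end = arm_end + w2
                too_long = (end - start + 1) > 27
                end[too_long] = start[too_long] + 26
                chroms = np.array(
                    [locus.placements[i].chrom for i in copy_idx], dtype=object
                )
                emit(chroms, start, end,
                     np.full(n, locus.interval.strand, dtype=object),
                     spec.sample_id, n)

            # tier-dirt injections: out-of-length reads invisible to the
            # informative-read tracks but counted among all mapped reads
            if locus.dirt == "straddle":
                m = int(rng.poisson(config.straddle_rate * 2 * lam))
                if m:
                    lengths = rng.integers(30, 35, size=m)
                    center = (locus.interval.start + locus.interval.end) // 2
                    centers = center + rng.integers(-1, 2, size=m)
                    start = centers - lengths // 2
                    end = start + lengths - 1
                    emit(np.full(m, locus.interval.chrom, dtype=object), start, end,
                         np.full(m, locus.interval.strand, dtype=object),
                         spec.sample_id, m)
            elif locus.dirt == "oversize":
                m = int(rng.poisson(config.oversize_rate * 2 * lam))
                if m:
                    lengths = rng.integers(30, 35, size=m)
                    left = rng.random(size=m) < 0.5
                    start = np.where(
                        left,
                        locus.arm5.end - lengths + 1,
                        locus.arm3.start,
                    )
                    end = start + lengths - 1
                    emit(np.full(m, locus.interval.chrom, dtype=object), start, end,
                         np.full(m, locus.interval.strand, dtype=object),
                         spec.sample_id, m)

        # repeat-derived reads (informative length, but inside repeats)
        n_rep = int(rng.poisson(config.repeat_read_fraction * spec.depth))
        if n_rep and sim.repeats:
            which = rng.integers(0, len(sim.repeats), size=n_rep)
            lengths = rng.choice(_INF_LENGTHS, size=n_rep, p=_INF_LENGTH_WEIGHTS)
            starts = np.empty(n_rep, dtype=np.int64)
            chroms = np.empty(n_rep, dtype=object)
            strands = np.empty(n_rep, dtype=object)
            for i, r_idx in enumerate(which):
                iv = sim.repeats[r_idx].interval
                hi = max(iv.end - int(lengths[i]) + 1, iv.start)
                starts[i] = int(rng.integers(iv.start, hi + 1))
                chroms[i] = iv.chrom
                strands[i] = "+" if rng.random() < 0.5 else "-"
            emit(chroms, starts, starts + lengths - 1, strands, spec.sample_id, n_rep)

        # out-of-length and background noise, outside the locus buffers
        n_out = int(rng.poisson(config.outlength_fraction * spec.depth))
        if n_out:
            chroms, starts = _sample_noise_positions(rng, segments, n_out)
            lengths = rng.choice(_OUT_LENGTHS, size=n_out)
            strands = np.where(rng.random(size=n_out) < 0.5, "+", "-").astype(object)
            emit(chroms, starts, starts + lengths - 1, strands, spec.sample_id, n_out)
        n_bg = int(rng.poisson(config.background_fraction * spec.depth))
        if n_bg:
            chroms, starts = _sample_noise_positions(rng, segments, n_bg)
            lengths = rng.choice(_INF_LENGTHS, size=n_bg, p=_INF_LENGTH_WEIGHTS)
            strands = np.where(rng.random(size=n_bg) < 0.5, "+", "-").astype(object)
            emit(chroms, starts, starts + lengths - 1, strands, spec.sample_id, n_bg)

    frame = pd.DataFrame(
        {
            "chrom": np.concatenate(rows_chrom) if rows_chrom else np.array([], dtype=object),
            "start": np.concatenate(rows_start) if rows_start else np.array([], dtype=np.int64),
            "end": np.concatenate(rows_end) if rows_end else np.array([], dtype=np.int64),
            "strand": np.concatenate(rows_strand) if rows_strand else np.array([], dtype=object),
            "sample_id": np.concatenate(rows_sample) if rows_sample else np.array([], dtype=object),
        }
    )
    frame["length"] = frame["end"] - frame["start"] + 1
    return frame


def simulate_fastq(
    sim: SimulatedData,
    reads: pd.DataFrame,
    *,
    adapter: str,
    n_records: int = 200,
    tail_length: int = 6,
) -> list[tuple[str, str, list[int]]]:
    """Emit raw-read FASTQ records for a subset of simulated mapped reads.

    Each record is the read's genomic sequence followed by the adapter and a
    low-quality random tail, so quality trimming plus adapter clipping
    recovers the original insert.
    """
    from .discovery import extract_sequence

    rng = np.random.default_rng([sim.config.seed, 2])
    subset = reads.head(n_records)
    records = []
    for i, row in enumerate(subset.itertuples(index=False)):
        iv = GenomeInterval(row.chrom, int(row.start), int(row.end), row.strand)
        insert = extract_sequence(sim.genome, iv)
        tail = _random_seq(rng, tail_length)
        seq = insert + adapter + tail
        quals = (
            [38] * len(insert)
            + [36] * len(adapter)
            + [int(q) for q in rng.integers(2, 20, size=tail_length)]
        )
        records.append((f"simread-{i + 1}", seq, quals))
    return records


# ---------------------------------------------------------------------------
# file emission


def write_simulation(
    sim: SimulatedData, reads: pd.DataFrame, out_dir: str | Path
) -> dict[str, Path]:
    """Write genome.fa, known.gff3, rmsk.tsv, truth.tsv, groups.tsv and
    per-sample BED files under ``out_dir``; returns the path manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reads_dir = out_dir / "reads"
    reads_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = out_dir / "genome.fa"
    mio.write_fasta(sim.genome, paths["genome"])
    paths["known"] = out_dir / "known.gff3"
    mio.write_mirna_gff3(sim.known, paths["known"])
    paths["repeats"] = out_dir / "rmsk.tsv"
    mio.write_repeats(sim.repeats, paths["repeats"])
    paths["truth"] = out_dir / "truth.tsv"
    sim.truth.to_tsv(paths["truth"])
    paths["groups"] = out_dir / "groups.tsv"
    mio.write_groups(sim.config.groups(), paths["groups"])
    for spec in sim.config.samples:
        sub = reads[reads["sample_id"] == spec.sample_id]
        path = reads_dir / f"{spec.sample_id}.bed"
        mio.write_mapped_reads_frame(sub, path)
        paths[f"reads/{spec.sample_id}"] = path
    return paths
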