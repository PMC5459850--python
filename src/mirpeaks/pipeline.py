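"""End-to-end orchestration: filter -> discover -> quantify -> tier -> diffexp.

Every stage is a pure function of its inputs, the parameter objects and the
seed; the manifest records a content checksum per artifact so identical
configurations reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as mio
from .core import ReadIndex
from .diffexp import DiffExpParams, calls_to_frame, count_directions, extremum_fold_change_classify
from .discovery import (
    HairpinParams,
    PeakCallingParams,
    build_rpm_track,
    call_candidates,
    filter_candidates,
    union_candidates,
)
from .expression import Feature, build_expression_matrix, candidate_features, merge_duplicate_expression
from .preprocess import FilterParams, select_informative_frame, summaries_to_frame, summarize_library
from .simulate import SimConfig, simulate_genome, simulate_reads, write_simulation
from .tiering import TierParams, assign_tier

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: Path
    genome: Path | None = None
    known_gff3: Path | None = None
    repeats_tsv: Path | None = None
    reads_dir: Path | None = None
    groups_tsv: Path | None = None
    seed: int = 0
    simulate: SimConfig | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    peak_params: PeakCallingParams = field(default_factory=PeakCallingParams)
    hairpin_params: HairpinParams = field(default_factory=HairpinParams)
    tier_params: TierParams = field(default_factory=TierParams)
    diffexp_params: DiffExpParams = field(default_factory=DiffExpParams)
    max_occurrences: int = 15
    split_threshold: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw: dict[str, Any] = yaml.safe_load(handle) or {}
        kwargs: dict[str, Any] = {}
        for key in ("out_dir", "genome", "known_gff3", "repeats_tsv", "reads_dir",
                    "groups_tsv"):
            if raw.get(key) is not None:
                kwargs[key] = Path(raw[key])
        for key in ("seed", "max_occurrences", "split_threshold"):
            if key in raw:
                kwargs[key] = int(raw[key])
        section_types = {
            "filter_params": FilterParams,
            "peak_params": PeakCallingParams,
            "hairpin_params": HairpinParams,
            "tier_params": TierParams,
            "diffexp_params": DiffExpParams,
        }
        for key, cls_ in section_types.items():
            if key in raw:
                kwargs[key] = cls_(**raw[key])
        if "simulate" in raw:
            sim_raw = dict(raw["simulate"] or {})
            sim_raw.setdefault("seed", kwargs.get("seed", 0))
            kwargs["simulate"] = SimConfig(**sim_raw)
        if "out_dir" not in kwargs:
            raise ValueError(f"{path}: config must set out_dir")
        return cls(**kwargs)

    def validate_inputs(self) -> None:
        """Fail before any stage runs if a referenced input is missing."""
        if self.simulate is not None:
            return  # inputs are generated
        missing = [
            str(p)
            for p in (self.genome, self.known_gff3, self.repeats_tsv,
                      self.reads_dir, self.groups_tsv)
            if p is None or not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing pipeline inputs: {missing}")


@dataclass
class Manifest:
    entries: list[tuple[str, str]] = field(default_factory=list)  # (path, sha256)

    def add(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.entries.append((str(path), digest))

    def to_tsv(self, path: Path) -> None:
        pd.DataFrame(self.entries, columns=["artifact", "sha256"]).to_csv(
            path, sep="\t", index=False
        )


def run_all(config: PipelineConfig) -> Manifest:
    """Execute the full pipeline and return the output manifest."""
    config.validate_inputs()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest()

    # --- stage 0: simulate (optional)
    if config.simulate is not None:
        sim_config = dataclasses.replace(config.simulate, seed=config.seed)
        sim = simulate_genome(sim_config)
        reads_frame = simulate_reads(sim)
        sim_dir = out_dir / "sim"
        paths = write_simulation(sim, reads_frame, sim_dir)
        config = dataclasses.replace(
            config,
            genome=paths["genome"],
            known_gff3=paths["known"],
            repeats_tsv=paths["repeats"],
            reads_dir=sim_dir / "reads",
            groups_tsv=paths["groups"],
        )
        for path in paths.values():
            manifest.add(path)
        logger.info("simulate: %d reads in %d samples", len(reads_frame),
                    reads_frame["sample_id"].nunique())

    genome = mio.read_fasta(config.genome)
    known = mio.read_mirna_gff3(config.known_gff3)
    repeats = mio.read_repeats(config.repeats_tsv)
    groups = mio.read_groups(config.groups_tsv)

    # --- stage 1: filter to informative reads, per-library summaries
    all_by_sample: dict[str, pd.DataFrame] = {}
    informative_by_sample: dict[str, pd.DataFrame] = {}
    summaries = []
    for bed in sorted(Path(config.reads_dir).glob("*.bed")):
        sample_id = bed.stem
        frame = mio.read_mapped_reads_frame(bed)
        informative = select_informative_frame(frame, repeats, config.filter_params)
        all_by_sample[sample_id] = frame
        informative_by_sample[sample_id] = informative
        summaries.append(
            summarize_library(frame, informative, known, sample_id=sample_id)
        )
        logger.info(
            "filter[%s]: %d mapped -> %d informative", sample_id, len(frame),
            len(informative),
        )
    if not all_by_sample:
        raise FileNotFoundError(f"no .bed read files under {config.reads_dir}")
    summary_path = out_dir / "summary.tsv"
    summaries_to_frame(summaries).to_csv(summary_path, sep="\t", index=False)
    manifest.add(summary_path)
    informative_path = out_dir / "informative.bed"
    informative_all = pd.concat(informative_by_sample.values(), ignore_index=True)
    mio.write_mapped_reads_frame(informative_all, informative_path)
    manifest.add(informative_path)
    informative_totals = {s: len(f) for s, f in informative_by_sample.items()}

    # --- stage 2: discovery (per-group tracks, union, filters)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    candidate_sets = []
    for group in sorted(set(groups.values())):
        members = [s for s, g in groups.items() if g == group]
        pooled = pd.concat(
            [informative_by_sample[s] for s in members], ignore_index=True
        )
        total = sum(informative_totals[s] for s in members)
        track = build_rpm_track(
            pooled, total, group_id=group, chrom_lengths=chrom_lengths
        )
        group_candidates = call_candidates(track, config.peak_params)
        logger.info("discover[%s]: %d double-peak loci", group, len(group_candidates))
        candidate_sets.append(group_candidates)
    candidates = union_candidates(candidate_sets)
    candidates = filter_candidates(
        candidates,
        known,
        repeats,
        genome,
        max_occurrences=config.max_occurrences,
        hairpin_params=config.hairpin_params,
        excluded_repeat_classes=config.filter_params.excluded_repeat_classes,
    )
    logger.info("discover: %d retained candidates", len(candidates))

    # --- stage 3: digital expression
    all_indexes = {s: ReadIndex(f) for s, f in all_by_sample.items()}
    informative_indexes = {s: ReadIndex(f) for s, f in informative_by_sample.items()}

    mature_features = [
        Feature(ann.id, ann.interval) for ann in known if ann.kind == "mature"
    ]
    known_matrix = build_expression_matrix(
        mature_features, all_indexes, informative_totals
    )
    known_matrix_path = out_dir / "known_expression.tsv"
    known_matrix.to_tsv(known_matrix_path)
    manifest.add(known_matrix_path)

    candidate_level_features = [Feature(c.id, c.interval) for c in candidates]
    candidate_matrix = build_expression_matrix(
        candidate_level_features, all_indexes, informative_totals
    )
    merged_matrix = merge_duplicate_expression(candidates, genome, candidate_matrix)
    merged_path = out_dir / "novel_premirna_expression.tsv"
    merged_matrix.to_tsv(merged_path)
    manifest.add(merged_path)

    shoulder_features = candidate_features(candidates, config.split_threshold)
    novel_matrix = build_expression_matrix(
        shoulder_features, all_indexes, informative_totals
    )
    novel_path = out_dir / "novel_shoulder_expression.tsv"
    novel_matrix.to_tsv(novel_path)
    manifest.add(novel_path)

    # --- stage 4: tier classification (counts pooled across all samples)
    pooled_all = ReadIndex(pd.concat(all_by_sample.values(), ignore_index=True))
    pooled_informative = ReadIndex(
        pd.concat(informative_by_sample.values(), ignore_index=True)
    )
    tier_rows = []
    for cand in candidates:
        assign_tier(cand, pooled_all, pooled_informative, config.tier_params)
        scores = cand.tier_scores
        tier_rows.append(
            {
                "candidate_id": cand.id,
                "chrom": cand.interval.chrom,
                "start": cand.interval.start,
                "end": cand.interval.end,
                "strand": cand.interval.strand,
                "n_all": scores.n_all,
                "n_informative": scores.n_informative,
                "informative_ratio": scores.informative_ratio,
                "stemloop_l": scores.stemloop_l,
                "stemloop_r": scores.stemloop_r,
                "stemloop_m": scores.stemloop_m,
                "stemloop_score": scores.stemloop_score,
                "tier": cand.tier,
            }
        )
    tier_path = out_dir / "tiered.tsv"
    pd.DataFrame(tier_rows).to_csv(tier_path, sep="\t", index=False)
    manifest.add(tier_path)

    candidates_path = out_dir / "candidates.gff3"
    from .core import MirnaAnnotation

    mio.write_mirna_gff3(
        [MirnaAnnotation(c.id, "pre_mirna", c.interval) for c in candidates],
        candidates_path,
    )
    manifest.add(candidates_path)

    # --- stage 5: differential expression (known matures + novel shoulders)
    for name, matrix in (("known", known_matrix), ("novel", novel_matrix)):
        calls = extremum_fold_change_classify(matrix, groups, config.diffexp_params)
        counts = count_directions(calls)
        logger.info(
            "diffexp[%s]: %d up in PSC, %d up in EF, %d not significant",
            name, counts.n_up_psc, counts.n_up_ef, counts.n_not_significant,
        )
        calls_path = out_dir / f"diffexp_{name}.tsv"
        calls_to_frame(calls).to_csv(calls_path, sep="\t", index=False)
        manifest.add(calls_path)

    manifest_path = out_dir / "manifest.tsv"
    manifest.to_tsv(manifest_path)
    return manifest
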