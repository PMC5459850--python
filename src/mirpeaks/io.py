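"""Readers and writers for the pipeline's external formats.

Formats handled here: miRBase-dialect GFF3 (annotation), BED6 (mapped reads),
UCSC rmsk-style TSV (repeats), fixedStep wiggle (coverage), FASTA (genome) and
FASTQ (raw reads). BED's 0-based half-open coordinates are converted to the
package-wide 1-based closed convention at this boundary and back on write, so
the two conversions compose to the identity.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, TYPE_CHECKING

import pandas as pd
from Bio import SeqIO

from .core import (
    GenomeInterval,
    MappedRead,
    MirnaAnnotation,
    RepeatRecord,
    frame_to_reads,
    reads_to_frame,
)

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type checkers
    from .discovery import RpmTrack

logger = logging.getLogger(__name__)

_GFF3_KIND = {"miRNA_primary_transcript": "pre_mirna", "miRNA": "mature"}
_KIND_GFF3 = {v: k for k, v in _GFF3_KIND.items()}


class Gff3ParseError(ValueError):
    """Raised for malformed GFF3 input; names the offending line number."""


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field.strip().split(";"):
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_mirna_gff3(path: str | Path) -> list[MirnaAnnotation]:
    """Read a miRBase-dialect GFF3 file.

    ``miRNA_primary_transcript`` features map to pre-miRNAs and ``miRNA``
    features to mature arms; ``Derives_from`` (or ``Parent``) resolves the
    mature -> pre-miRNA linkage. Unknown feature types are skipped with a
    warning; malformed lines raise :class:`Gff3ParseError`.
    """
    annotations: list[MirnaAnnotation] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise Gff3ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature_type, start, end, _score, strand, _phase, attr = fields
            if feature_type not in _GFF3_KIND:
                logger.warning(
                    "%s: line %d: skipping unknown feature type %r",
                    path, lineno, feature_type,
                )
                continue
            try:
                interval = GenomeInterval(chrom, int(start), int(end), strand)
            except ValueError as exc:
                raise Gff3ParseError(f"{path}: line {lineno}: {exc}") from exc
            attrs = _parse_gff3_attributes(attr)
            record_id = attrs.get("ID") or attrs.get("Name")
            if not record_id:
                raise Gff3ParseError(f"{path}: line {lineno}: record has no ID attribute")
            parent = attrs.get("Derives_from") or attrs.get("Parent")
            annotations.append(
                MirnaAnnotation(
                    id=record_id,
                    kind=_GFF3_KIND[feature_type],
                    interval=interval,
                    parent=parent,
                )
            )
    return annotations


def write_mirna_gff3(annotations: Iterable[MirnaAnnotation], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for ann in annotations:
            attrs = [f"ID={ann.id}", f"Name={ann.id}"]
            if ann.parent:
                attrs.append(f"Derives_from={ann.parent}")
            iv = ann.interval
            handle.write(
                "\t".join(
                    [
                        iv.chrom,
                        ".",
                        _KIND_GFF3[ann.kind],
                        str(iv.start),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_mapped_reads_frame(path: str | Path) -> pd.DataFrame:
    """Read BED6 mapped reads into the bulk DataFrame representation.

    BED name holds the sample id; 0-based half-open spans become 1-based
    closed. Records with end <= start are rejected with a logged warning.
    """
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "bed_start", "bed_end", "sample_id", "score", "strand"],
            dtype={"chrom": str, "bed_start": "int64", "bed_end": "int64",
                   "sample_id": str, "strand": str},
        )
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame(
            columns=["chrom", "bed_start", "bed_end", "sample_id", "score", "strand"]
        )
    bad = frame["bed_end"] <= frame["bed_start"]
    if bad.any():
        for row in frame.index[bad]:
            logger.warning(
                "%s: rejecting BED record %d with end <= start (%d <= %d)",
                path, row, frame.at[row, "bed_end"], frame.at[row, "bed_start"],
            )
        frame = frame[~bad]
    out = pd.DataFrame(
        {
            "chrom": frame["chrom"].astype(str),
            "start": frame["bed_start"].astype("int64") + 1,
            "end": frame["bed_end"].astype("int64"),
            "strand": frame["strand"].astype(str),
            "sample_id": frame["sample_id"].astype(str),
        }
    )
    out["length"] = out["end"] - out["start"] + 1
    return out.reset_index(drop=True)


def read_mapped_reads(path: str | Path) -> list[MappedRead]:
    """BED6 -> list of :class:`MappedRead` (see :func:`read_mapped_reads_frame`)."""
    return frame_to_reads(read_mapped_reads_frame(path))


def write_mapped_reads_frame(frame: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "start": frame["start"].astype("int64") - 1,
            "end": frame["end"].astype("int64"),
            "name": frame["sample_id"],
            "score": 0,
            "strand": frame["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_mapped_reads(reads: Iterable[MappedRead], path: str | Path) -> None:
    write_mapped_reads_frame(reads_to_frame(reads), path)


def read_repeats(path: str | Path) -> list[RepeatRecord]:
    """Read an rmsk-style TSV: chrom, start0, end, strand, repeat_name, repeat_class."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            RepeatRecord(
                interval=GenomeInterval(row.chrom, int(row.start0) + 1, int(row.end), row.strand),
                repeat_class=str(row.repeat_class),
                repeat_name=str(row.repeat_name),
            )
        )
    return records


def write_repeats(repeats: Iterable[RepeatRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": r.interval.chrom,
            "start0": r.interval.start - 1,
            "end": r.interval.end,
            "strand": r.interval.strand,
            "repeat_name": r.repeat_name,
            "repeat_class": r.repeat_class,
        }
        for r in repeats
    ]
    pd.DataFrame(rows, columns=["chrom", "start0", "end", "strand", "repeat_name",
                                "repeat_class"]).to_csv(path, sep="\t", index=False)


def write_wiggle(track: "RpmTrack", path: str | Path) -> None:
    """Write a strand-split fixedStep wiggle file.

    Each (chromosome, strand) pair gets a ``track`` declaration named
    ``<group>|<strand>``; zero-valued positions are omitted so only the
    nonzero runs appear as fixedStep blocks. Values carry 6 significant
    digits.
    """
    import numpy as np

    with open(path, "w") as handle:
        for (chrom, strand), values in sorted(track.coverage.items()):
            nz = np.flatnonzero(values)
            if len(nz) == 0:
                continue
            handle.write(
                f'track type=wiggle_0 name="{track.group_id}|{strand}"\n'
            )
            # break into consecutive runs
            breaks = np.flatnonzero(np.diff(nz) > 1)
            run_starts = np.concatenate(([0], breaks + 1))
            run_ends = np.concatenate((breaks, [len(nz) - 1]))
            for a, b in zip(run_starts, run_ends):
                pos = int(nz[a]) + 1  # array index 0 is genomic position 1
                handle.write(f"fixedStep chrom={chrom} start={pos} step=1\n")
                for idx in nz[a : b + 1]:
                    handle.write(f"{values[idx]:.6g}\n")


def read_wiggle(path: str | Path) -> dict[tuple[str, str, str], dict[int, float]]:
    """Read a wiggle written by :func:`write_wiggle`.

    Returns ``{(group, chrom, strand): {position: value}}`` with 1-based
    positions; intended for round-trip checks and small tracks.
    """
    out: dict[tuple[str, str, str], dict[int, float]] = {}
    group = strand = chrom = None
    pos = 0
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith("track"):
                name = line.split('name="', 1)[1].rstrip('"')
                group, strand = name.rsplit("|", 1)
            elif line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"])
                if int(fields.get("step", 1)) != 1:
                    raise ValueError(f"{path}: only step=1 wiggle is supported")
            else:
                key = (group, chrom, strand)
                out.setdefault(key, {})[pos] = float(line)
                pos += 1
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file fully into memory as upper-case strings."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fasta:
        return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    """Read FASTQ as (read id, sequence, Phred qualities) tuples."""
    return [
        (rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(records: Iterable[tuple[str, str, list[int]]], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    seq_records = []
    for read_id, seq, quals in records:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        seq_records.append(rec)
    SeqIO.write(seq_records, str(path), "fastq")


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a sample -> group TSV (columns: sample_id, group)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(frame["sample_id"], frame["group"]))


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups.keys()), "group": list(groups.values())}
    ).to_csv(path, sep="\t", index=False)
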