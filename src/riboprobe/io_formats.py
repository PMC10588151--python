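"""Readers and writers for the formats the pipeline touches.

FASTA (references, probes, reads), FASTQ (reads), SAM/BAM (alignments),
a per-base depth TSV, and BED6 for regions. All interval I/O preserves the
internal 0-based half-open convention; probe FASTA headers alone carry
1-based inclusive coordinates.
"""
from __future__ import annotations

import logging
import os
import re
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .errors import DataError, ParseError, ValidationError
from .models import (
    CoverageTrack,
    ProbeRecord,
    ProbeSet,
    ReadRecord,
    ReferenceRecord,
    ReferenceSet,
    Region,
)

logger = logging.getLogger(__name__)

_PROBE_HEADER = re.compile(r"^(?P<pid>[^|]+)\|(?P<ref>[^|]+)\|(?P<s>\d+)-(?P<e>\d+)$")


def read_fasta(path: str | os.PathLike) -> list[ReferenceRecord]:
    """Read a DNA FASTA into :class:`ReferenceRecord` objects.

    Sequences are upper-cased; characters outside ACGTN are rejected with
    their position. An empty file yields an empty list.
    """
    records: list[ReferenceRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for rec in parsed:
        seq = str(rec.seq).upper()
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(ReferenceRecord(ref_id=rec.id, sequence=seq))
    return records


def read_reference_set(path: str | os.PathLike) -> ReferenceSet:
    return ReferenceSet(read_fasta(path))


def coverage_from_alignments(
    alignment_path: str | os.PathLike,
    references: ReferenceSet,
    sample_id: str,
    min_mapq: int = 0,
) -> list[CoverageTrack]:
    """Per-base depth from a SAM/BAM file, one track per reference.

    Depth at a position is the number of aligned read bases covering it:
    primary, mapped, non-supplementary alignments with MAPQ >= ``min_mapq``
    only. Deletions and skips in a read contribute nothing at the deleted
    positions; insertions contribute nothing anywhere. References with no
    alignments get an all-zero track.
    """
    depths = {
        ref_id: np.zeros(references.length(ref_id), dtype=np.int64)
        for ref_id in references
    }
    try:
        af = pysam.AlignmentFile(str(path := Path(alignment_path)), "r", check_sq=False)
    except (OSError, ValueError) as exc:
        raise ParseError(f"{alignment_path}: {exc}") from exc
    with af:
        unknown = [r for r in af.references if r not in references]
        if unknown:
            raise DataError(
                f"{path}: alignment reference(s) absent from the reference set: "
                + ", ".join(sorted(unknown))
            )
        try:
            for aln in af.fetch(until_eof=True):
                if (
                    aln.is_unmapped
                    or aln.is_secondary
                    or aln.is_supplementary
                    or aln.mapping_quality < min_mapq
                ):
                    continue
                positions = aln.get_reference_positions()
                if positions:
                    np.add.at(depths[aln.reference_name], positions, 1)
        except OSError as exc:  # truncated BAM surfaces here
            raise ParseError(f"{path}: {exc}") from exc
    return [
        CoverageTrack(ref_id=ref_id, sample_id=sample_id, depth=depths[ref_id])
        for ref_id in references
    ]


def read_depth_table(
    path: str | os.PathLike,
    references: ReferenceSet,
    sample_id: str,
) -> list[CoverageTrack]:
    """Read a TSV of (ref_id, position, depth) rows into coverage tracks.

    Positions are 0-based and need not be exhaustive: missing positions are
    depth 0. One track is returned per reference that appears in the table;
    an empty table yields an empty list.
    """
    try:
        df = pd.read_csv(str(path), sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    except (OSError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    required = {"ref_id", "position", "depth"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: depth table needs columns ref_id, position, depth "
            f"(found {list(df.columns)})"
        )
    if df.empty:
        return []
    for col in ("position", "depth"):
        try:
            df[col] = df[col].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: non-integer {col}: {exc}") from exc
    if (df["depth"] < 0).any():
        raise ValidationError(f"{path}: negative depth values")
    if df.duplicated(subset=["ref_id", "position"]).any():
        dup = df[df.duplicated(subset=["ref_id", "position"])].iloc[0]
        raise ValidationError(
            f"{path}: duplicate row for ({dup['ref_id']}, {dup['position']})"
        )
    tracks: list[CoverageTrack] = []
    for ref_id, sub in df.groupby("ref_id", sort=False):
        if ref_id not in references:
            raise DataError(f"{path}: unknown reference {ref_id!r}")
        length = references.length(str(ref_id))
        if (sub["position"] >= length).any() or (sub["position"] < 0).any():
            raise ValidationError(
                f"{path}: position out of bounds for {ref_id!r} (length {length})"
            )
        depth = np.zeros(length, dtype=np.int64)
        depth[sub["position"].to_numpy()] = sub["depth"].to_numpy()
        tracks.append(CoverageTrack(ref_id=str(ref_id), sample_id=sample_id, depth=depth))
    return tracks


def write_depth_table(tracks: Iterable[CoverageTrack], path: str | os.PathLike) -> None:
    """Write nonzero positions of the given tracks as a depth TSV."""
    rows = []
    for t in tracks:
        nz = np.flatnonzero(t.depth)
        for pos in nz:
            rows.append((t.ref_id, int(pos), int(t.depth[pos])))
    df = pd.DataFrame(rows, columns=["ref_id", "position", "depth"])
    df.to_csv(str(path), sep="\t", index=False)


def probe_fasta_header(probe: ProbeRecord) -> str:
    """``probe_id|source_ref|start1-end1`` with 1-based inclusive coordinates."""
    return f"{probe.probe_id}|{probe.source_ref}|{probe.source_start + 1}-{probe.source_end}"


def write_probe_fasta(probe_set: ProbeSet | Sequence[ProbeRecord], path: str | os.PathLike) -> None:
    probes = list(probe_set)
    if not probes:
        logger.warning("writing empty probe FASTA to %s", path)
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f">{probe_fasta_header(p)}\n{p.sequence}\n")


def read_probe_fasta(
    path: str | os.PathLike, references: ReferenceSet | None = None
) -> list[ProbeRecord]:
    """Parse a probe FASTA written by :func:`write_probe_fasta`.

    If ``references`` is given, each probe is checked to be the reverse
    complement of its recorded source substring.
    """
    probes: list[ProbeRecord] = []
    for rec in read_fasta(path):
        m = _PROBE_HEADER.match(rec.ref_id)
        if not m:
            raise ParseError(
                f"{path}: probe header {rec.ref_id!r} is not "
                "'probe_id|source_ref|start1-end1'"
            )
        probe = ProbeRecord(
            probe_id=m["pid"],
            sequence=rec.sequence,
            source_ref=m["ref"],
            source_start=int(m["s"]) - 1,
            source_end=int(m["e"]),
        )
        if references is not None and not probe.matches_reference(references):
            raise ValidationError(
                f"{path}: probe {probe.probe_id} does not match the reverse "
                f"complement of {probe.source_ref}[{probe.source_start}:"
                f"{probe.source_end}]"
            )
        probes.append(probe)
    return probes


def write_bed(regions: Sequence[Region], path: str | os.PathLike) -> None:
    """BED6: ref, start, end (0-based half-open), name, rounded mean depth, '+'."""
    with open(path, "w") as fh:
        for r in regions:
            score = int(round(r.mean_depth))
            fh.write(f"{r.ref_id}\t{r.start}\t{r.end}\t{r.region_id}\t{score}\t+\n")


def write_region_fasta(regions: Sequence[Region], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in regions:
            if r.sequence is None:
                raise ValidationError(f"region {r.region_id} has no sequence")
            fh.write(f">{r.region_id}\n{r.sequence}\n")


def read_reads(path: str | os.PathLike) -> list[ReadRecord]:
    """Read FASTQ (.fastq/.fq) or FASTA reads; quality is discarded."""
    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    try:
        return [
            ReadRecord(read_id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), fmt)
        ]
    except (ValueError, FileNotFoundError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def footprints_from_alignments(
    path: str | os.PathLike, min_mapq: int = 0
) -> dict[str, tuple[str, int, int]]:
    """Read-id -> (ref, start, end) reference footprints from a SAM/BAM file.

    Primary, mapped, non-supplementary alignments only; the footprint is the
    aligned reference span [reference_start, reference_end).
    """
    footprints: dict[str, tuple[str, int, int]] = {}
    try:
        af = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    with af:
        for aln in af.fetch(until_eof=True):
            if (
                aln.is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or aln.mapping_quality < min_mapq
            ):
                continue
            footprints[aln.query_name] = (
                aln.reference_name,
                aln.reference_start,
                aln.reference_end,
            )
    return footprints


def write_fastq(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    """Write reads as FASTQ with a constant 'I' quality string."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
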