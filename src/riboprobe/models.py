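"""Core domain types shared across the pipeline.

Coordinate convention: every interval in memory is 0-based, half-open
``[start, end)`` on the sense strand of an rRNA reference. The only place
1-based inclusive coordinates appear is in probe FASTA headers, for human
readability.
"""
from __future__ import annotations

import re
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError, ConfigError

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_REF_ALPHABET = re.compile(r"^[ACGTN]+$")
_PROBE_ALPHABET = re.compile(r"^[ACGT]+$")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an upper-case DNA string (N allowed)."""
    return sequence.translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceRecord:
    """One rRNA reference sequence (e.g. an SSU or LSU gene)."""

    ref_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"reference {self.ref_id!r}: empty sequence")
        if not _REF_ALPHABET.match(self.sequence):
            bad = next(
                i for i, c in enumerate(self.sequence) if c not in "ACGTN"
            )
            raise ValidationError(
                f"reference {self.ref_id!r}: disallowed character "
                f"{self.sequence[bad]!r} at position {bad} (DNA over ACGTN only)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


class ReferenceSet(Mapping[str, ReferenceRecord]):
    """Ordered, id-unique collection of reference sequences."""

    def __init__(self, records: Iterable[ReferenceRecord]):
        self._records: dict[str, ReferenceRecord] = {}
        for rec in records:
            if rec.ref_id in self._records:
                raise ValidationError(f"duplicate reference id {rec.ref_id!r}")
            self._records[rec.ref_id] = rec

    def __getitem__(self, ref_id: str) -> ReferenceRecord:
        return self._records[ref_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def sequence(self, ref_id: str) -> str:
        return self._records[ref_id].sequence

    def length(self, ref_id: str) -> int:
        return self._records[ref_id].length

    @property
    def records(self) -> list[ReferenceRecord]:
        return list(self._records.values())


@dataclass
class CoverageTrack:
    """Per-base read depth over one reference for one sample."""

    ref_id: str
    sample_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValidationError("depth must be a 1-D array")
        if self.depth.size and self.depth.min() < 0:
            raise ValidationError(
                f"track {self.sample_id}/{self.ref_id}: negative depth"
            )

    @property
    def length(self) -> int:
        return int(self.depth.size)


@dataclass(frozen=True)
class Region:
    """A candidate undepleted interval on a reference.

    ``mean_depth`` is the arithmetic mean of per-base depth over the interval;
    ``sample_ids`` records which samples contributed evidence; ``sequence`` is
    the sense-strand reference substring, filled when regions are pooled.
    """

    ref_id: str
    start: int
    end: int
    mean_depth: float
    sample_ids: frozenset[str] = frozenset()
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"region {self.ref_id}:{self.start}-{self.end}: need 0 <= start < end"
            )
        if self.mean_depth < 0:
            raise ValidationError("region mean_depth must be >= 0")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"region {self.region_id}: sequence length {len(self.sequence)} "
                f"!= interval length {self.length}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def region_id(self) -> str:
        return f"{self.ref_id}:{self.start}-{self.end}"


@dataclass(frozen=True)
class ProbeRecord:
    """A 50-nt antisense DNA oligo with its sense-strand source interval."""

    probe_id: str
    sequence: str
    source_ref: str
    source_start: int
    source_end: int
    orientation: str = "antisense"

    def __post_init__(self) -> None:
        if self.orientation != "antisense":
            raise ValidationError("probe orientation is always 'antisense'")
        if not _PROBE_ALPHABET.match(self.sequence):
            raise ValidationError(
                f"probe {self.probe_id}: sequence must be ACGT-only"
            )
        if self.source_end - self.source_start != len(self.sequence):
            raise ValidationError(
                f"probe {self.probe_id}: source interval length "
                f"{self.source_end - self.source_start} != sequence length "
                f"{len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def matches_reference(self, references: ReferenceSet) -> bool:
        """True iff the probe is the reverse complement of its source substring."""
        sense = references.sequence(self.source_ref)[
            self.source_start : self.source_end
        ]
        return self.sequence == reverse_complement(sense)


@dataclass(frozen=True)
class DesignParameters:
    """Tunable constants of the probe-design pipeline.

    Defaults reproduce the published design: regions separated by at most
    3 uncovered bases are merged, regions with mean depth below 500x are
    dropped, the top 50 regions per sample are pooled, redundancy and
    existing-probe exclusion use an 80% identity threshold, and probes are
    50 nt antisense oligos.
    """

    min_base_depth: int = 1
    max_merge_gap: int = 3
    min_region_depth: float = 500.0
    top_k_per_sample: int = 50
    identity_threshold: float = 0.80
    probe_length: int = 50

    def __post_init__(self) -> None:
        if self.min_base_depth < 1:
            raise ConfigError("min_base_depth must be >= 1")
        if self.max_merge_gap < 0:
            raise ConfigError("max_merge_gap must be >= 0")
        if self.min_region_depth <= 0:
            raise ConfigError("min_region_depth must be positive")
        if self.top_k_per_sample < 1:
            raise ConfigError("top_k_per_sample must be >= 1")
        if not 0 < self.identity_threshold <= 1:
            raise ConfigError("identity_threshold must be in (0, 1]")
        if self.probe_length < 1:
            raise ConfigError("probe_length must be positive")


@dataclass(frozen=True)
class AlignmentResult:
    """Pairwise alignment summary used for redundancy/exclusion decisions.

    ``identity`` is matches / aligned_columns where terminal gap columns are
    excluded and internal gap columns count as non-matching.
    """

    query_id: str
    target_id: str
    identity: float
    aligned_columns: int
    matches: int
    query_strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.matches <= self.aligned_columns:
            raise ValidationError("need 0 <= matches <= aligned_columns")
        if self.query_strand not in "+-":
            raise ValidationError("query_strand must be '+' or '-'")


@dataclass
class ProbeSet:
    """Ordered probe collection with its design parameters and provenance."""

    probes: list[ProbeRecord]
    params: DesignParameters = field(default_factory=DesignParameters)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise ValidationError("probe ids must be unique")

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self) -> Iterator[ProbeRecord]:
        return iter(self.probes)

    def source_intervals(self) -> dict[str, list[tuple[int, int]]]:
        """Merged union of probe source intervals, per reference."""
        by_ref: dict[str, list[tuple[int, int]]] = {}
        for p in self.probes:
            by_ref.setdefault(p.source_ref, []).append(
                (p.source_start, p.source_end)
            )
        merged: dict[str, list[tuple[int, int]]] = {}
        for ref, ivs in by_ref.items():
            ivs.sort()
            out = [ivs[0]]
            for s, e in ivs[1:]:
                if s <= out[-1][1]:
                    out[-1] = (out[-1][0], max(out[-1][1], e))
                else:
                    out.append((s, e))
            merged[ref] = out
        return merged


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read, optionally carrying a synthetic truth label."""

    read_id: str
    sequence: str
    truth_label: str | None = None  # "rRNA" or "clean"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"read {self.read_id!r}: empty sequence")
        if self.truth_label not in (None, "rRNA", "clean"):
            raise ValidationError("truth_label must be 'rRNA', 'clean' or None")


@dataclass
class DepletionReport:
    """rRNA content of a read set and predicted residual after depletion."""

    total_reads: int
    rrna_reads: int
    depletable_reads: int
    per_reference: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.rrna_reads <= self.total_reads:
            raise ValidationError("need 0 <= rrna_reads <= total_reads")
        if not 0 <= self.depletable_reads <= self.rrna_reads:
            raise ValidationError("need 0 <= depletable_reads <= rrna_reads")

    @property
    def rrna_fraction(self) -> float:
        return self.rrna_reads / self.total_reads if self.total_reads else 0.0

    @property
    def residual_rrna_fraction(self) -> float:
        if not self.total_reads:
            return 0.0
        return (self.rrna_reads - self.depletable_reads) / self.total_reads

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "rrna_reads": self.rrna_reads,
            "rrna_fraction": self.rrna_fraction,
            "depletable_reads": self.depletable_reads,
            "residual_rrna_fraction": self.residual_rrna_fraction,
            "per_reference": self.per_reference,
        }
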