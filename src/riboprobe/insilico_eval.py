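"""In-silico rRNA content and depletion prediction.

A read is called rRNA when it shares at least one canonical k-mer with the
rRNA reference index (the simplest membership rule; the sensitivity/
specificity trade-offs of production classifiers are out of scope). RNase H
depletion is modeled geometrically: an rRNA read is depletable when at least
``min_overlap_fraction`` of its reference footprint lies under the union of
probe source intervals on its reference. This deliberately ignores
hybridization thermodynamics and cross-hybridization between homologous
references.
"""
from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from .errors import ConfigError, DataError
from .models import (
    DepletionReport,
    ProbeRecord,
    ProbeSet,
    ReadRecord,
    ReferenceSet,
    reverse_complement,
)

logger = logging.getLogger(__name__)

Footprint = tuple[str, int, int]


@dataclass(frozen=True)
class KmerIndex:
    """Set of canonical k-mers over an rRNA reference set."""

    k: int
    kmers: frozenset[str]

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.kmers

    def __len__(self) -> int:
        return len(self.kmers)


def canonical_kmer(kmer: str) -> str | None:
    """Lexicographic min of a k-mer and its reverse complement; None if non-ACGT."""
    if not set(kmer) <= frozenset("ACGT"):
        return None
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def iter_canonical_kmers(sequence: str, k: int):
    for i in range(len(sequence) - k + 1):
        canon = canonical_kmer(sequence[i : i + k])
        if canon is not None:
            yield canon


def build_kmer_index(references: ReferenceSet, k: int = 31) -> KmerIndex:
    """Canonical k-mer set over all references; k-mers containing N skipped."""
    if k < 1 or k % 2 == 0:
        raise ConfigError(f"k must be a positive odd integer, got {k}")
    if len(references) == 0:
        raise DataError("cannot index an empty reference set")
    if all(rec.length < k for rec in references.records):
        raise DataError(f"k={k} is larger than every reference")
    kmers: set[str] = set()
    for rec in references.records:
        kmers.update(iter_canonical_kmers(rec.sequence, k))
    return KmerIndex(k=k, kmers=frozenset(kmers))


@dataclass
class ClassificationResult:
    """Partition of a read set into rRNA and clean."""

    labels: dict[str, str] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return len(self.labels)

    @property
    def rrna_ids(self) -> list[str]:
        return [r for r, lab in self.labels.items() if lab == "rRNA"]

    @property
    def rrna_fraction(self) -> float:
        return len(self.rrna_ids) / self.total_reads if self.labels else 0.0


def classify_reads(
    reads: Sequence[ReadRecord], index: KmerIndex
) -> ClassificationResult:
    """Call a read rRNA iff it shares >= 1 canonical k-mer with the index.

    Reads shorter than k are classified clean (and logged).
    """
    labels: dict[str, str] = {}
    short = 0
    for read in reads:
        if len(read.sequence) < index.k:
            labels[read.read_id] = "clean"
            short += 1
            continue
        labels[read.read_id] = (
            "rRNA"
            if any(km in index for km in iter_canonical_kmers(read.sequence, index.k))
            else "clean"
        )
    if short:
        logger.info("%d reads shorter than k=%d classified clean", short, index.k)
    return ClassificationResult(labels=labels)


def _overlap_with_union(
    footprint: tuple[int, int], intervals: Sequence[tuple[int, int]]
) -> int:
    s, e = footprint
    return sum(max(0, min(e, ie) - max(s, is_)) for is_, ie in intervals)


def predicted_depletion(
    rrna_read_footprints: Mapping[str, Footprint],
    probe_set: ProbeSet | Sequence[ProbeRecord],
    total_reads: int,
    min_overlap_fraction: float = 0.5,
    references: ReferenceSet | None = None,
) -> DepletionReport:
    """Predict residual rRNA after depleting with a probe set.

    ``rrna_read_footprints`` maps each rRNA read id to its (ref, start, end)
    reference footprint (from alignment or synthetic truth). A read is
    depletable when the union of probe source intervals on its reference
    covers at least ``min_overlap_fraction`` of its footprint (inclusive).
    """
    if not isinstance(probe_set, ProbeSet):
        probe_set = ProbeSet(probes=list(probe_set))
    probe_union = probe_set.source_intervals()
    rrna_reads = len(rrna_read_footprints)
    if rrna_reads > total_reads:
        raise DataError("more rRNA footprints than total reads")
    depletable = 0
    per_ref: dict[str, dict[str, int]] = {}
    for read_id, (ref, s, e) in rrna_read_footprints.items():
        if s < 0 or e <= s:
            raise DataError(f"read {read_id}: invalid footprint ({s},{e})")
        if references is not None:
            if ref not in references:
                raise DataError(f"read {read_id}: unknown reference {ref!r}")
            if e > references.length(ref):
                raise DataError(
                    f"read {read_id}: footprint outside reference bounds"
                )
        stats = per_ref.setdefault(ref, {"rrna_reads": 0, "depletable_reads": 0})
        stats["rrna_reads"] += 1
        overlap = _overlap_with_union((s, e), probe_union.get(ref, ()))
        if overlap >= min_overlap_fraction * (e - s):
            depletable += 1
            stats["depletable_reads"] += 1
    return DepletionReport(
        total_reads=total_reads,
        rrna_reads=rrna_reads,
        depletable_reads=depletable,
        per_reference=per_ref,
    )


def evaluate_depletion(
    reads: Sequence[ReadRecord],
    references: ReferenceSet,
    probe_set: ProbeSet | Sequence[ProbeRecord],
    footprints: Mapping[str, Footprint],
    k: int = 31,
    min_overlap_fraction: float = 0.5,
) -> tuple[ClassificationResult, DepletionReport]:
    """Classify reads against the references, then predict depletion.

    Reads classified rRNA but lacking a footprint are counted as
    non-depletable (their residual contribution is conservative).
    """
    index = build_kmer_index(references, k)
    classification = classify_reads(reads, index)
    rrna_ids = classification.rrna_ids
    known = {r: footprints[r] for r in rrna_ids if r in footprints}
    missing = len(rrna_ids) - len(known)
    if missing:
        logger.warning(
            "%d rRNA-classified reads have no footprint; counted as residual",
            missing,
        )
    report = predicted_depletion(
        known,
        probe_set,
        total_reads=classification.total_reads,
        min_overlap_fraction=min_overlap_fraction,
        references=references,
    )
    # fold footprint-less rRNA reads back into the totals as non-depletable
    if missing:
        report = DepletionReport(
            total_reads=report.total_reads,
            rrna_reads=report.rrna_reads + missing,
            depletable_reads=report.depletable_reads,
            per_reference=report.per_reference,
        )
    return classification, report


def plot_depletion(reports: Mapping[str, DepletionReport], path: str) -> None:
    """Stacked-fraction bar plot: depleted rRNA, residual rRNA, clean."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(reports)
    depleted = [
        r.depletable_reads / r.total_reads if r.total_reads else 0.0
        for r in reports.values()
    ]
    residual = [r.residual_rrna_fraction for r in reports.values()]
    clean = [1.0 - r.rrna_fraction for r in reports.values()]
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(labels), 4))
    ax.bar(labels, residual, label="residual rRNA", color="#c0392b")
    ax.bar(labels, depleted, bottom=residual, label="depleted rRNA", color="#f1c40f")
    bottoms = [r + d for r, d in zip(residual, depleted)]
    ax.bar(labels, clean, bottom=bottoms, label="non-rRNA", color="#2980b9")
    ax.set_ylabel("fraction of reads")
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
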