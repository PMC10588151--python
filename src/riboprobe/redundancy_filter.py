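"""Redundancy removal and existing-probe exclusion by percent identity.

Two alignment modes are used, both with affine gaps (match +1, mismatch -1,
gap open -2, gap extend -1):

* region-vs-region redundancy uses semi-global alignment: the shorter
  sequence must align end to end while the longer sequence's terminal
  overhangs are gap-free, so length differences do not penalize identity but
  a short spurious overlap cannot masquerade as redundancy;
* probe-vs-region exclusion uses local alignment, with the extra requirement
  that the aligned span covers at least 80% of the probe length so a short
  spurious hit cannot eliminate a region.

Percent identity is matches / aligned columns, where columns outside the
aligned core (terminal gaps) are excluded and internal gap columns count as
non-matching. Both strands are always tested: probes are antisense, and the
orientation of a region relative to a probe catalogue is not guaranteed.
"""
from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

import networkx as nx
from Bio import Align

from .errors import ContractError, DataError
from .models import AlignmentResult, Region, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


DEFAULT_SCORING = AlignmentScoring()


def _make_aligner(scoring: AlignmentScoring, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    if mode == "semi-global":
        # target = the longer sequence; only its terminal overhangs are free
        aligner.mode = "global"
        aligner.end_deletion_score = 0.0
    elif mode == "local":
        aligner.mode = "local"
    else:
        raise ContractError(f"unknown alignment mode {mode!r}")
    return aligner


def _identity_from_alignment(seq_a: str, seq_b: str, alignment) -> tuple[int, int, int, int]:
    """(matches, columns, span_a, span_b) over the aligned core.

    Columns are counted from the first to the last aligned base pair;
    internal gaps contribute non-matching columns, terminal gaps none.
    """
    blocks_a, blocks_b = alignment.aligned
    if len(blocks_a) == 0:
        return 0, 0, 0, 0
    matches = 0
    columns = 0
    prev_a_end = prev_b_end = None
    for (a_s, a_e), (b_s, b_e) in zip(blocks_a.tolist(), blocks_b.tolist()):
        if prev_a_end is not None:
            columns += (a_s - prev_a_end) + (b_s - prev_b_end)  # internal gaps
        columns += a_e - a_s
        matches += sum(
            x == y for x, y in zip(seq_a[a_s:a_e], seq_b[b_s:b_e])
        )
        prev_a_end, prev_b_end = a_e, b_e
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    return matches, columns, span_a, span_b


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    query_id: str = "query",
    target_id: str = "target",
    query_strand: str = "+",
) -> AlignmentResult:
    """Semi-global percent identity between two DNA sequences.

    The shorter sequence is aligned end to end against the longer one, whose
    terminal overhangs carry no gap penalty; identity is matches over the
    aligned columns between the first and last aligned base pair. Symmetric
    by construction: the roles are assigned canonically (longer sequence is
    the target; lexicographic order breaks length ties), so
    identity(a, b) == identity(b, a).
    """
    if not seq_a or not seq_b:
        raise DataError("pairwise_identity: empty sequence")
    x, y = sorted((seq_a, seq_b), key=lambda s: (len(s), s))
    target, query = y, x  # longer (or lexicographically larger) is the target
    aligner = _make_aligner(scoring, "semi-global")
    alignment = aligner.align(target, query)[0]
    matches, columns, _, _ = _identity_from_alignment(target, query, alignment)
    identity = matches / columns if columns else 0.0
    return AlignmentResult(
        query_id=query_id,
        target_id=target_id,
        identity=identity,
        aligned_columns=columns,
        matches=matches,
        query_strand=query_strand,
    )


def best_strand_identity(
    seq_a: str,
    seq_b: str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentResult:
    """Higher of the forward and reverse-complement identities ('+' on ties)."""
    fwd = pairwise_identity(seq_a, seq_b, scoring, query_id, target_id, "+")
    rev = pairwise_identity(
        seq_a, reverse_complement(seq_b), scoring, query_id, target_id, "-"
    )
    return rev if rev.identity > fwd.identity else fwd


def redundancy_components(
    regions: Sequence[Region],
    identity_threshold: float,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> list[list[int]]:
    """Single-linkage components of the >= threshold identity graph.

    Nodes are region indices; an edge joins any pair whose best-strand
    identity reaches the threshold (inclusive). Components are returned
    sorted by their smallest member index.
    """
    for r in regions:
        if r.sequence is None:
            raise DataError(f"region {r.region_id} has no sequence")
    graph = nx.Graph()
    graph.add_nodes_from(range(len(regions)))
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            res = best_strand_identity(
                regions[i].sequence, regions[j].sequence, scoring
            )
            if res.identity >= identity_threshold:
                graph.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: c[0])
    return comps


def cluster_redundant(
    regions: Sequence[Region],
    identity_threshold: float,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> list[Region]:
    """Keep one representative per redundancy component.

    The representative is the deepest region in its component; ties go to
    the longer region, then the smaller (ref_id, start). Survivors keep
    their original input order.
    """
    comps = redundancy_components(regions, identity_threshold, scoring)
    keep: set[int] = set()
    for comp in comps:
        rep = min(
            comp,
            key=lambda i: (
                -regions[i].mean_depth,
                -regions[i].length,
                regions[i].ref_id,
                regions[i].start,
            ),
        )
        keep.add(rep)
        if len(comp) > 1:
            dropped = [regions[i].region_id for i in comp if i != rep]
            logger.info(
                "redundant cluster: kept %s, dropped %s",
                regions[rep].region_id,
                ", ".join(dropped),
            )
    return [r for i, r in enumerate(regions) if i in keep]


@dataclass(frozen=True)
class ProbeHit:
    """Record of an existing probe eliminating a candidate region."""

    region_id: str
    probe_id: str
    identity: float
    strand: str


def _local_probe_hit(
    probe_seq: str,
    region_seq: str,
    scoring: AlignmentScoring,
) -> tuple[float, int]:
    """(identity, probe_span) of the best local alignment of probe vs region."""
    aligner = _make_aligner(scoring, "local")
    alignments = aligner.align(region_seq, probe_seq)
    if len(alignments) == 0:
        return 0.0, 0
    alignment = alignments[0]
    matches, columns, _, span_probe = _identity_from_alignment(
        region_seq, probe_seq, alignment
    )
    return (matches / columns if columns else 0.0), span_probe


def exclude_probe_covered(
    regions: Sequence[Region],
    existing_probes: Sequence[tuple[str, str]],
    identity_threshold: float,
    min_span_fraction: float = 0.8,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> tuple[list[Region], list[ProbeHit]]:
    """Drop regions already covered by an existing probe set.

    ``existing_probes`` is a sequence of (probe_id, sequence) pairs (e.g.
    parsed from a probe FASTA). A region is eliminated when any probe aligns
    locally, on either strand, at identity >= the threshold over a span of at
    least ``min_span_fraction`` of the probe length. Returns the survivors in
    input order together with one hit record per eliminated region.
    """
    if not existing_probes:
        logger.warning("empty existing probe set: no regions excluded")
        return list(regions), []
    survivors: list[Region] = []
    hits: list[ProbeHit] = []
    for region in regions:
        if region.sequence is None:
            raise DataError(f"region {region.region_id} has no sequence")
        hit: ProbeHit | None = None
        for probe_id, probe_seq in existing_probes:
            min_span = min_span_fraction * len(probe_seq)
            for strand, target in (
                ("+", region.sequence),
                ("-", reverse_complement(region.sequence)),
            ):
                identity, span = _local_probe_hit(probe_seq, target, scoring)
                if identity >= identity_threshold and span >= min_span:
                    hit = ProbeHit(region.region_id, probe_id, identity, strand)
                    break
            if hit:
                break
        if hit:
            hits.append(hit)
            logger.info(
                "region %s eliminated by probe %s (identity %.3f, strand %s)",
                hit.region_id,
                hit.probe_id,
                hit.identity,
                hit.strand,
            )
        else:
            survivors.append(region)
    return survivors, hits
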