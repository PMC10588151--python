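"""From per-sample coverage to the pooled list of abundant undepleted regions.

The per-sample stages mirror the published loop: call maximal covered runs,
merge runs separated by a few uncovered bases, score each run by mean depth
and drop anything below the 500x floor, keep the top 50 per sample, then pool
across samples and merge overlapping coordinates.
"""
from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np

from .errors import ContractError, DataError
from .models import CoverageTrack, DesignParameters, ReferenceSet, Region

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

# Ranking key used everywhere a depth order is needed: deepest first, ties to
# the longer interval, then smallest (ref_id, start).
def _rank_key(r: Region):
    return (-r.mean_depth, -(r.end - r.start), r.ref_id, r.start)


def call_covered_intervals(
    track: CoverageTrack, min_base_depth: int = 1
) -> list[Interval]:
    """Maximal runs of consecutive positions with depth >= ``min_base_depth``.

    Returned sorted by start and pairwise disjoint; empty list if nothing is
    covered.
    """
    mask = track.depth >= min_base_depth
    padded = np.concatenate(([False], mask, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _check_sorted_disjoint(intervals: Sequence[Interval]) -> None:
    for (s, e), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e:
            raise ContractError(
                f"intervals must be sorted and disjoint; got ({s},{e}) then ({s2},{e2})"
            )
    for s, e in intervals:
        if s >= e:
            raise ContractError(f"empty interval ({s},{e})")


def merge_proximal(
    intervals: Sequence[Interval], max_merge_gap: int
) -> list[Interval]:
    """Union adjacent intervals whose uncovered gap is <= ``max_merge_gap``.

    Applied transitively, so chains of small gaps collapse into one interval.
    Input must be sorted and disjoint.
    """
    _check_sorted_disjoint(intervals)
    if not intervals:
        return []
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s - merged[-1][1] <= max_merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def score_and_filter(
    intervals: Sequence[Interval],
    track: CoverageTrack,
    min_region_depth: float,
) -> list[Region]:
    """Score intervals by mean depth; drop those strictly below the floor.

    A region whose mean depth equals the floor exactly survives ("remove any
    with less than" the floor). Survivors are sorted deepest-first.
    """
    regions = []
    for s, e in intervals:
        if e > track.length:
            raise ContractError(
                f"interval ({s},{e}) exceeds track length {track.length}"
            )
        mean = float(track.depth[s:e].mean())
        if mean < min_region_depth:
            continue
        regions.append(
            Region(
                ref_id=track.ref_id,
                start=s,
                end=e,
                mean_depth=mean,
                sample_ids=frozenset({track.sample_id}),
            )
        )
    regions.sort(key=_rank_key)
    return regions


def top_k(regions: Sequence[Region], top_k_per_sample: int) -> list[Region]:
    """The k deepest regions of one sample, in rank order.

    Ties break toward the longer interval, then the smaller (ref_id, start).
    """
    return sorted(regions, key=_rank_key)[:top_k_per_sample]


def pool_and_merge(
    per_sample_regions: Sequence[Sequence[Region]],
    references: ReferenceSet,
) -> list[Region]:
    """Pool regions across samples and union overlapping/touching intervals.

    The merged region's score is the maximum of its contributors' mean depths
    (strongest single-sample evidence), its sample set is the union of
    contributors, and its sense sequence is extracted from the reference.
    Output is sorted by (ref_id, start).
    """
    flat = [r for sample in per_sample_regions for r in sample]
    for r in flat:
        if r.ref_id not in references:
            raise DataError(f"region {r.region_id}: unknown reference")
        if r.end > references.length(r.ref_id):
            raise DataError(
                f"region {r.region_id} exceeds reference length "
                f"{references.length(r.ref_id)}"
            )
    pooled: list[Region] = []
    by_ref: dict[str, list[Region]] = {}
    for r in flat:
        by_ref.setdefault(r.ref_id, []).append(r)
    for ref_id in sorted(by_ref):
        group = sorted(by_ref[ref_id], key=lambda r: (r.start, r.end))
        cur_s, cur_e = group[0].start, group[0].end
        cur_depth = group[0].mean_depth
        cur_samples = set(group[0].sample_ids)
        for r in group[1:]:
            if r.start <= cur_e:  # touching counts as overlapping
                cur_e = max(cur_e, r.end)
                cur_depth = max(cur_depth, r.mean_depth)
                cur_samples |= r.sample_ids
            else:
                pooled.append(
                    _pooled_region(references, ref_id, cur_s, cur_e, cur_depth, cur_samples)
                )
                cur_s, cur_e, cur_depth = r.start, r.end, r.mean_depth
                cur_samples = set(r.sample_ids)
        pooled.append(
            _pooled_region(references, ref_id, cur_s, cur_e, cur_depth, cur_samples)
        )
    return pooled


def _pooled_region(references, ref_id, start, end, depth, samples) -> Region:
    return Region(
        ref_id=ref_id,
        start=start,
        end=end,
        mean_depth=depth,
        sample_ids=frozenset(samples),
        sequence=references.sequence(ref_id)[start:end],
    )


def discover_sample_regions(
    tracks: Sequence[CoverageTrack],
    params: DesignParameters,
) -> list[Region]:
    """Run the per-sample stages over all of one sample's tracks.

    Calls covered runs, merges proximal runs, applies the depth filter, and
    keeps the top-k regions across the whole sample (all references jointly,
    matching the published per-donor selection).
    """
    sample_ids = {t.sample_id for t in tracks}
    if len(sample_ids) > 1:
        raise ContractError(f"tracks from multiple samples: {sorted(sample_ids)}")
    scored: list[Region] = []
    for track in tracks:
        intervals = call_covered_intervals(track, params.min_base_depth)
        intervals = merge_proximal(intervals, params.max_merge_gap)
        scored.extend(score_and_filter(intervals, track, params.min_region_depth))
    selected = top_k(scored, params.top_k_per_sample)
    logger.info(
        "sample %s: %d regions above %gx, %d kept",
        next(iter(sample_ids), "?"),
        len(scored),
        params.min_region_depth,
        len(selected),
    )
    return selected
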