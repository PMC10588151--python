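"""End-to-end orchestration of the probe-design stages.

The CLI is a thin wrapper around :func:`design_probeset`, which chains
per-sample region discovery, cross-sample pooling, redundancy clustering,
existing-probe exclusion, and probe tiling, recording per-stage counts for
the run manifest.
"""
from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from .errors import ConfigError
from .models import CoverageTrack, DesignParameters, ProbeSet, ReferenceSet, Region
from .probe_design import design_probes
from .redundancy_filter import ProbeHit, cluster_redundant, exclude_probe_covered
from .region_discovery import discover_sample_regions, pool_and_merge


@dataclass
class DesignResult:
    """Intermediate and final products of one design run."""

    per_sample_regions: dict[str, list[Region]]
    pooled_regions: list[Region]
    representatives: list[Region]
    survivors: list[Region]
    exclusion_hits: list[ProbeHit]
    probe_set: ProbeSet
    counts: dict[str, int] = field(default_factory=dict)


def design_probeset(
    references: ReferenceSet,
    tracks_by_sample: Mapping[str, Sequence[CoverageTrack]],
    params: DesignParameters = DesignParameters(),
    existing_probes: Sequence[tuple[str, str]] = (),
) -> DesignResult:
    """Run the full design loop over per-sample coverage tracks.

    ``existing_probes`` is the (probe_id, sequence) list of the probe set to
    exclude against (the standard depletion probes, plus any prior design
    iteration when supplementing).
    """
    if not tracks_by_sample:
        raise ConfigError("at least one sample is required")
    per_sample: dict[str, list[Region]] = {}
    for sample_id, tracks in tracks_by_sample.items():
        per_sample[sample_id] = discover_sample_regions(list(tracks), params)
    pooled = pool_and_merge(list(per_sample.values()), references)
    representatives = cluster_redundant(pooled, params.identity_threshold)
    survivors, hits = exclude_probe_covered(
        representatives, existing_probes, params.identity_threshold
    )
    probe_set = design_probes(survivors, references, params)
    counts = {
        "samples": len(per_sample),
        "per_sample_regions_total": sum(len(v) for v in per_sample.values()),
        "pooled_regions": len(pooled),
        "non_redundant_regions": len(representatives),
        "regions_after_probe_exclusion": len(survivors),
        "regions_eliminated_by_existing_probes": len(hits),
        "probes_emitted": len(probe_set),
    }
    return DesignResult(
        per_sample_regions=per_sample,
        pooled_regions=pooled,
        representatives=representatives,
        survivors=survivors,
        exclusion_hits=hits,
        probe_set=probe_set,
        counts=counts,
    )
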