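"""Tile 50-nt antisense probes across the final region set.

Tiling is non-overlapping from the region start; a remainder of at least
half a probe length earns one extra window right-anchored at the region end
(which may overlap the previous window). Regions shorter than one probe are
extended symmetrically on the reference, clipped at reference ends. Windows
containing non-ACGT bases are shifted by up to +-5 nt to find a clean frame,
else skipped.
"""
from __future__ import annotations

import logging
from collections.abc import Sequence

from .errors import DataError
from .models import (
    DesignParameters,
    ProbeRecord,
    ProbeSet,
    ReferenceSet,
    Region,
    reverse_complement,
)

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")
# Shift order when escaping an ambiguous base: smallest magnitude first,
# leftward before rightward at equal magnitude.
_SHIFTS = [0] + [s for k in range(1, 6) for s in (-k, k)]


def antisense(dna: str) -> str:
    """Reverse complement of a strict-ACGT DNA string."""
    if not set(dna) <= _ACGT:
        bad = next(c for c in dna if c not in _ACGT)
        raise DataError(f"antisense: non-ACGT character {bad!r}")
    return reverse_complement(dna)


def tile_region(
    region: Region,
    references: ReferenceSet,
    probe_length: int = 50,
) -> list[tuple[int, int]]:
    """Source windows (0-based half-open, sense strand) for one region."""
    if region.ref_id not in references:
        raise DataError(f"region {region.region_id}: unknown reference")
    ref_len = references.length(region.ref_id)
    length = region.length
    if length < probe_length:
        if ref_len < probe_length:
            logger.warning(
                "region %s skipped: reference shorter than one probe",
                region.region_id,
            )
            return []
        # symmetric extension, clipped at reference bounds
        start = region.start - (probe_length - length) // 2
        start = max(0, min(start, ref_len - probe_length))
        return [(start, start + probe_length)]
    windows = [
        (region.start + i * probe_length, region.start + (i + 1) * probe_length)
        for i in range(length // probe_length)
    ]
    remainder = length % probe_length
    if remainder * 2 >= probe_length:
        windows.append((region.end - probe_length, region.end))
    return windows


def _clean_window(
    ref_seq: str, start: int, end: int, ref_len: int
) -> tuple[int, int] | None:
    """Shift a window by up to +-5 nt until its sequence is ACGT-only."""
    for shift in _SHIFTS:
        s, e = start + shift, end + shift
        if s < 0 or e > ref_len:
            continue
        if set(ref_seq[s:e]) <= _ACGT:
            return s, e
    return None


def design_probes(
    regions: Sequence[Region],
    references: ReferenceSet,
    params: DesignParameters = DesignParameters(),
) -> ProbeSet:
    """Emit the antisense probe set for the post-exclusion region list.

    Exact duplicate probe sequences across regions are emitted once (first
    occurrence wins); probes are sorted by source coordinates and named with
    zero-padded serials. Deterministic: identical inputs give identical output.
    """
    seen: dict[str, tuple[str, int, int, str]] = {}  # sequence -> (ref,s,e,region)
    for region in regions:
        ref_seq = references.sequence(region.ref_id)
        ref_len = references.length(region.ref_id)
        for start, end in tile_region(region, references, params.probe_length):
            window = _clean_window(ref_seq, start, end, ref_len)
            if window is None:
                logger.warning(
                    "window %s:%d-%d skipped: ambiguous bases with no clean "
                    "shift within +-5 nt",
                    region.ref_id,
                    start,
                    end,
                )
                continue
            s, e = window
            probe_seq = antisense(ref_seq[s:e])
            if probe_seq not in seen:
                seen[probe_seq] = (region.ref_id, s, e, region.region_id)
    ordered = sorted(seen.items(), key=lambda kv: (kv[1][0], kv[1][1]))
    probes: list[ProbeRecord] = []
    provenance: dict[str, str] = {}
    for i, (probe_seq, (ref_id, s, e, region_id)) in enumerate(ordered, start=1):
        probe_id = f"probe_{i:04d}"
        probes.append(
            ProbeRecord(
                probe_id=probe_id,
                sequence=probe_seq,
                source_ref=ref_id,
                source_start=s,
                source_end=e,
            )
        )
        provenance[probe_id] = region_id
    return ProbeSet(probes=probes, params=params, provenance=provenance)
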