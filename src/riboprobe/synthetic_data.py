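"""Synthetic rRNA communities, planted-hotspot coverage, and labeled reads.

Every pipeline stage can be exercised against known ground truth without any
downloads: a multi-species community is simulated by substituting an ancestral
SSU/LSU pair at a controlled per-site divergence, coverage tracks carry
planted high-depth "undepleted" hotspots over a low background, and reads are
drawn either uniformly or from the hotspot intervals with exact truth labels
and reference footprints. The mutation/error model is substitution-only (no
indels), which keeps footprint bookkeeping exact.
"""
from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError
from .insilico_eval import build_kmer_index, iter_canonical_kmers
from .models import CoverageTrack, ReadRecord, ReferenceRecord, ReferenceSet

_BASES = np.frombuffer(b"ACGT", dtype="S1")

Hotspot = tuple[int, int, int]  # start, end, target mean depth


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a simulated multi-species rRNA community.

    ``divergence`` is the per-site substitution probability between the
    common ancestor and each species; two species then differ at roughly
    ``2*d*(1-d) + ...`` of sites, i.e. expected pairwise identity
    ``(1-d)^2 + d^2/3``. The default 0.15 puts inter-species identity near
    0.73, safely below the 0.80 redundancy threshold so that distinct
    species need distinct probes.
    """

    n_species: int
    ssu_length: int = 1500
    lsu_length: int = 2900
    divergence: float = 0.15
    abundances: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")
        if self.ssu_length < 1 or self.lsu_length < 1:
            raise ConfigError("subunit lengths must be positive")
        if not 0 <= self.divergence <= 0.3:
            raise ConfigError("divergence must be in [0, 0.3]")
        if self.abundances is not None:
            ab = np.asarray(self.abundances, dtype=float)
            if ab.size != self.n_species:
                raise ConfigError("abundances must have one weight per species")
            if (ab < 0).any():
                raise ConfigError("abundances must be non-negative")
            if abs(ab.sum() - 1.0) > 1e-9:
                raise ConfigError("abundances must sum to 1")

    def species_abundances(self) -> np.ndarray:
        if self.abundances is None:
            return np.full(self.n_species, 1.0 / self.n_species)
        return np.asarray(self.abundances, dtype=float)


@dataclass
class SyntheticTruth:
    """Ground truth for parameter-recovery and classifier tests."""

    # (sample_id, ref_id) -> list of (start, end, target depth)
    hotspot_intervals: dict[tuple[str, str], list[Hotspot]] = field(default_factory=dict)
    read_labels: dict[str, str] = field(default_factory=dict)
    read_footprints: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        merged = SyntheticTruth(
            hotspot_intervals={**self.hotspot_intervals, **other.hotspot_intervals},
            read_labels={**self.read_labels, **other.read_labels},
            read_footprints={**self.read_footprints, **other.read_footprints},
        )
        return merged

    def to_json(self, path: str) -> None:
        payload = {
            "hotspot_intervals": {
                f"{sample}\t{ref}": [list(h) for h in hs]
                for (sample, ref), hs in self.hotspot_intervals.items()
            },
            "read_labels": self.read_labels,
            "read_footprints": {
                rid: [ref, s, e] for rid, (ref, s, e) in self.read_footprints.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        truth = cls()
        for key, hs in payload.get("hotspot_intervals", {}).items():
            sample, ref = key.split("\t")
            truth.hotspot_intervals[(sample, ref)] = [tuple(h) for h in hs]
        truth.read_labels = dict(payload.get("read_labels", {}))
        truth.read_footprints = {
            rid: (ref, int(s), int(e))
            for rid, (ref, s, e) in payload.get("read_footprints", {}).items()
        }
        return truth


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _mutate(
    rng: np.random.Generator, ancestor: np.ndarray, rate: float
) -> tuple[np.ndarray, int]:
    """Per-site substitution at the given rate; substituted bases always change."""
    mask = rng.random(ancestor.size) < rate
    offsets = rng.integers(1, 4, size=int(mask.sum()), dtype=np.int8)
    derived = ancestor.copy()
    derived[mask] = (derived[mask] + offsets) % 4
    return derived, int(mask.sum())


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def simulate_community(spec: CommunitySpec) -> tuple[ReferenceSet, dict]:
    """Simulate SSU/LSU references for each species from a common ancestor.

    Deterministic given ``spec.seed``; returns the reference set and a
    lineage record (ancestral sequences plus per-reference substitution
    counts).
    """
    rng = np.random.default_rng(spec.seed)
    ancestors = {
        "SSU": _random_sequence(rng, spec.ssu_length),
        "LSU": _random_sequence(rng, spec.lsu_length),
    }
    records: list[ReferenceRecord] = []
    lineage: dict = {
        "ancestors": {su: _to_str(seq) for su, seq in ancestors.items()},
        "substitutions": {},
    }
    for i in range(spec.n_species):
        for subunit in ("SSU", "LSU"):
            derived, n_subs = _mutate(rng, ancestors[subunit], spec.divergence)
            ref_id = f"sp{i + 1:02d}_{subunit}"
            records.append(ReferenceRecord(ref_id=ref_id, sequence=_to_str(derived)))
            lineage["substitutions"][ref_id] = n_subs
    return ReferenceSet(records), lineage


def plant_coverage(
    references: ReferenceSet,
    hotspots: Mapping[str, Mapping[str, Sequence[Hotspot]]],
    background_depth: int = 0,
    seed: int = 0,
    jitter: float = 0.0,
) -> tuple[dict[str, list[CoverageTrack]], SyntheticTruth]:
    """Coverage tracks with planted hotspots over a flat background.

    ``hotspots`` maps sample_id -> ref_id -> disjoint (start, end, depth)
    intervals with depth strictly above the background. With ``jitter`` > 0
    each position gets an integer perturbation of up to +-``jitter`` of its
    target depth. Returns tracks per sample (every reference gets a track)
    and the planted truth.
    """
    if background_depth < 0:
        raise ConfigError("background_depth must be >= 0")
    if not 0 <= jitter <= 0.5:
        raise ConfigError("jitter must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    tracks: dict[str, list[CoverageTrack]] = {}

    def _fill(depth_array: np.ndarray, lo: int, hi: int, target: int) -> None:
        depth_array[lo:hi] = target
        if jitter > 0 and target > 0:
            amp = int(target * jitter)
            if amp:
                depth_array[lo:hi] += rng.integers(-amp, amp + 1, size=hi - lo)

    for sample_id, per_ref in hotspots.items():
        sample_tracks: list[CoverageTrack] = []
        for ref_id in references:
            length = references.length(ref_id)
            depth = np.zeros(length, dtype=np.int64)
            _fill(depth, 0, length, background_depth)
            spots = sorted(per_ref.get(ref_id, ()))
            prev_end = 0
            for s, e, d in spots:
                if not 0 <= s < e <= length:
                    raise DataError(
                        f"hotspot ({s},{e}) outside reference {ref_id!r}"
                    )
                if s < prev_end:
                    raise DataError(f"overlapping hotspots on {ref_id!r}")
                if d <= background_depth:
                    raise DataError(
                        f"hotspot depth {d} must exceed background {background_depth}"
                    )
                _fill(depth, s, e, d)
                prev_end = e
            if spots:
                truth.hotspot_intervals[(sample_id, ref_id)] = [tuple(h) for h in spots]
            np.maximum(depth, 0, out=depth)
            sample_tracks.append(
                CoverageTrack(ref_id=ref_id, sample_id=sample_id, depth=depth)
            )
        tracks[sample_id] = sample_tracks
    return tracks, truth


def simulate_reads(
    references: ReferenceSet,
    abundances: Sequence[float],
    n_reads: int,
    read_length: int = 76,
    error_rate: float = 0.0,
    clean_fraction: float = 0.0,
    seed: int = 0,
    k: int = 31,
    source_intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    max_clean_attempts: int = 100,
) -> tuple[list[ReadRecord], SyntheticTruth]:
    """Simulate labeled rRNA and clean reads.

    The read count is partitioned before sampling: exactly
    ``round(clean_fraction * n_reads)`` clean reads. rRNA reads are drawn
    from references proportionally to ``abundances`` (one weight per
    reference) with uniform start positions — restricted to
    ``source_intervals`` per reference when given — and per-base substitution
    errors at ``error_rate``. Clean reads are random sequences rejection-
    sampled to share no canonical k-mer with the reference index. Determinist
    given ``seed``.
    """
    ab = np.asarray(abundances, dtype=float)
    if ab.size != len(references) or (ab < 0).any() or ab.sum() <= 0:
        raise ConfigError("abundances must be non-negative, one per reference")
    ab = ab / ab.sum()
    if not 0 <= clean_fraction <= 1:
        raise ConfigError("clean_fraction must be in [0, 1]")
    shortest = min(rec.length for rec in references.records)
    if read_length > shortest:
        raise ConfigError(
            f"read_length {read_length} exceeds shortest reference ({shortest})"
        )
    ref_ids = list(references)
    windows: dict[str, list[tuple[int, int]]] = {}
    for ref_id in ref_ids:
        if source_intervals and ref_id in source_intervals:
            usable = [
                (s, e)
                for s, e in source_intervals[ref_id]
                if e - s >= read_length
            ]
            if not usable:
                raise ConfigError(
                    f"no source interval on {ref_id!r} can hold a "
                    f"{read_length}-nt read"
                )
            windows[ref_id] = usable
        else:
            windows[ref_id] = [(0, references.length(ref_id))]

    rng = np.random.default_rng(seed)
    n_clean = int(round(clean_fraction * n_reads))
    n_rrna = n_reads - n_clean
    truth = SyntheticTruth()
    reads: list[ReadRecord] = []

    encoded = {
        ref_id: np.frombuffer(
            references.sequence(ref_id).encode(), dtype="S1"
        )
        for ref_id in ref_ids
    }
    base_to_code = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}

    ref_choices = rng.choice(len(ref_ids), size=n_rrna, p=ab)
    serial = 0
    for ref_idx in ref_choices:
        ref_id = ref_ids[int(ref_idx)]
        ivs = windows[ref_id]
        widths = np.array([e - s - read_length + 1 for s, e in ivs], dtype=float)
        iv = ivs[int(rng.choice(len(ivs), p=widths / widths.sum()))]
        start = int(rng.integers(iv[0], iv[1] - read_length + 1))
        chunk = encoded[ref_id][start : start + read_length]
        codes = np.array([base_to_code.get(b, 0) for b in chunk], dtype=np.int8)
        if error_rate > 0:
            codes, _ = _mutate(rng, codes, error_rate)
        read_id = f"read_{serial:06d}"
        serial += 1
        reads.append(
            ReadRecord(read_id=read_id, sequence=_to_str(codes), truth_label="rRNA")
        )
        truth.read_labels[read_id] = "rRNA"
        truth.read_footprints[read_id] = (ref_id, start, start + read_length)

    if n_clean:
        index = build_kmer_index(references, k)
        for _ in range(n_clean):
            for attempt in range(max_clean_attempts):
                seq = _to_str(_random_sequence(rng, read_length))
                if not any(km in index for km in iter_canonical_kmers(seq, k)):
                    break
            else:
                raise DataError(
                    f"could not sample an index-disjoint clean read in "
                    f"{max_clean_attempts} attempts"
                )
            read_id = f"read_{serial:06d}"
            serial += 1
            reads.append(
                ReadRecord(read_id=read_id, sequence=seq, truth_label="clean")
            )
            truth.read_labels[read_id] = "clean"
    return reads, truth


@dataclass
class DemoBundle:
    """Everything the default synthetic demo produces, in memory."""

    references: ReferenceSet
    lineage: dict
    tracks_by_sample: dict[str, list[CoverageTrack]]
    coverage_truth: SyntheticTruth
    reads: list[ReadRecord]
    read_truth: SyntheticTruth
    abundances: np.ndarray

    @property
    def truth(self) -> SyntheticTruth:
        return self.coverage_truth.merge(self.read_truth)


def default_scenario(
    seed: int,
    n_species: int = 10,
    n_samples: int = 3,
    n_reads: int = 4000,
    read_length: int = 76,
    clean_fraction: float = 0.3,
    error_rate: float = 0.0,
    hotspots_per_ref: int = 2,
    depth_range: tuple[int, int] = (600, 1500),
    length_range: tuple[int, int] = (120, 220),
    background_depth: int = 0,
    jitter: float = 0.0,
    divergence: float = 0.15,
) -> DemoBundle:
    """The default synthetic study: community, hotspot coverage, and reads.

    Each reference carries ``hotspots_per_ref`` planted undepleted segments
    (120-220 nt, mean depth 600-1500x, shared across samples with per-sample
    depth draws), and rRNA reads are drawn from those segments — the
    situation the pipeline exists for: residual reads concentrate in the
    undepleted portions of each rRNA.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(4)]
    spec = CommunitySpec(n_species=n_species, divergence=divergence, seed=seeds[0])
    references, lineage = simulate_community(spec)
    rng = np.random.default_rng(seeds[1])

    intervals: dict[str, list[tuple[int, int]]] = {}
    for ref_id in references:
        length = references.length(ref_id)
        spots: list[tuple[int, int]] = []
        attempts = 0
        while len(spots) < hotspots_per_ref and attempts < 1000:
            attempts += 1
            size = int(rng.integers(length_range[0], length_range[1] + 1))
            start = int(rng.integers(0, length - size + 1))
            cand = (start, start + size)
            if all(cand[1] + 50 <= s or e + 50 <= cand[0] for s, e in spots):
                spots.append(cand)
        intervals[ref_id] = sorted(spots)

    hotspots: dict[str, dict[str, list[Hotspot]]] = {}
    for s in range(n_samples):
        sample_id = f"sample{s + 1:02d}"
        hotspots[sample_id] = {
            ref_id: [
                (iv[0], iv[1], int(rng.integers(depth_range[0], depth_range[1] + 1)))
                for iv in ivs
            ]
            for ref_id, ivs in intervals.items()
        }
    tracks, coverage_truth = plant_coverage(
        references,
        hotspots,
        background_depth=background_depth,
        seed=seeds[2],
        jitter=jitter,
    )
    ref_abundances = np.full(len(references), 1.0 / len(references))
    reads, read_truth = simulate_reads(
        references,
        ref_abundances,
        n_reads=n_reads,
        read_length=read_length,
        error_rate=error_rate,
        clean_fraction=clean_fraction,
        seed=seeds[3],
        source_intervals=intervals,
    )
    return DemoBundle(
        references=references,
        lineage=lineage,
        tracks_by_sample=tracks,
        coverage_truth=coverage_truth,
        reads=reads,
        read_truth=read_truth,
        abundances=ref_abundances,
    )
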