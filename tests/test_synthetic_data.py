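import numpy as np
import pytest

from riboprobe.errors import ConfigError, DataError
from riboprobe.models import DesignParameters
from riboprobe.region_discovery import (
    call_covered_intervals,
    merge_proximal,
    score_and_filter,
)
from riboprobe.synthetic_data import (
    CommunitySpec,
    SyntheticTruth,
    default_scenario,
    plant_coverage,
    simulate_community,
    simulate_reads,
)


class TestSimulateCommunity:
    def test_zero_divergence_reproduces_ancestor(self):
        refs, lineage = simulate_community(
            CommunitySpec(n_species=3, divergence=0.0, seed=1)
        )
        for subunit in ("SSU", "LSU"):
            ancestor = lineage["ancestors"][subunit]
            for i in range(3):
                assert refs.sequence(f"sp{i+1:02d}_{subunit}") == ancestor

    def test_same_seed_is_deterministic(self):
        spec = CommunitySpec(n_species=4, seed=7)
        refs_a, _ = simulate_community(spec)
        refs_b, _ = simulate_community(spec)
        assert [r.sequence for r in refs_a.records] == [
            r.sequence for r in refs_b.records
        ]

    def test_hamming_distance_within_binomial_bounds(self):
        spec = CommunitySpec(n_species=5, divergence=0.2, seed=11)
        refs, lineage = simulate_community(spec)
        ancestor = lineage["ancestors"]["SSU"]
        expected = 0.2 * 1500
        sigma = np.sqrt(1500 * 0.2 * 0.8)
        for i in range(5):
            derived = refs.sequence(f"sp{i+1:02d}_SSU")
            hamming = sum(a != b for a, b in zip(ancestor, derived))
            assert abs(hamming - expected) <= 3 * sigma
            assert hamming == lineage["substitutions"][f"sp{i+1:02d}_SSU"]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_species": 0},
            {"n_species": 2, "divergence": 0.4},
            {"n_species": 2, "abundances": (0.5, 0.6)},
            {"n_species": 2, "abundances": (1.2, -0.2)},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            CommunitySpec(**kwargs)


class TestPlantCoverage:
    @pytest.fixture()
    def refs(self):
        refs, _ = simulate_community(CommunitySpec(n_species=1, seed=2))
        return refs

    def test_exact_construction_without_jitter(self, refs):
        hotspots = {"s1": {"sp01_SSU": [(100, 250, 600)]}}
        tracks, truth = plant_coverage(refs, hotspots, background_depth=0, seed=0)
        track = {t.ref_id: t for t in tracks["s1"]}["sp01_SSU"]
        assert (track.depth[100:250] == 600).all()
        assert track.depth.sum() == 600 * 150
        assert truth.hotspot_intervals[("s1", "sp01_SSU")] == [(100, 250, 600)]

    def test_no_hotspots_gives_flat_background(self, refs):
        tracks, truth = plant_coverage(refs, {"s1": {}}, background_depth=7, seed=0)
        assert all((t.depth == 7).all() for t in tracks["s1"])
        assert truth.hotspot_intervals == {}

    def test_jitter_stays_within_band(self, refs):
        hotspots = {"s1": {"sp01_SSU": [(0, 500, 1000)]}}
        tracks, _ = plant_coverage(refs, hotspots, seed=3, jitter=0.1)
        spot = {t.ref_id: t for t in tracks["s1"]}["sp01_SSU"].depth[0:500]
        assert spot.min() >= 900 and spot.max() <= 1100
        assert (spot != 1000).any()

    def test_overlapping_hotspots_rejected(self, refs):
        with pytest.raises(DataError, match="overlapping"):
            plant_coverage(
                refs, {"s1": {"sp01_SSU": [(0, 100, 600), (50, 150, 700)]}}
            )

    def test_hotspot_depth_must_exceed_background(self, refs):
        with pytest.raises(DataError, match="background"):
            plant_coverage(
                refs, {"s1": {"sp01_SSU": [(0, 100, 50)]}}, background_depth=60
            )

    @pytest.mark.parametrize("depth, survives", [(500, True), (499, False)])
    def test_depth_filter_threshold_end_to_end(self, refs, depth, survives):
        hotspots = {"s1": {"sp01_SSU": [(100, 250, depth)]}}
        tracks, _ = plant_coverage(refs, hotspots, seed=0, jitter=0.0)
        track = {t.ref_id: t for t in tracks["s1"]}["sp01_SSU"]
        intervals = merge_proximal(call_covered_intervals(track, 1), 3)
        regions = score_and_filter(intervals, track, 500)
        assert bool(regions) is survives


class TestSimulateReads:
    @pytest.fixture()
    def refs(self):
        refs, _ = simulate_community(CommunitySpec(n_species=2, seed=4))
        return refs

    def uniform(self, refs):
        return np.full(len(refs), 1.0 / len(refs))

    def test_clean_fraction_zero_all_rrna(self, refs):
        reads, truth = simulate_reads(
            refs, self.uniform(refs), n_reads=50, clean_fraction=0.0, seed=1
        )
        assert all(r.truth_label == "rRNA" for r in reads)
        assert len(truth.read_footprints) == 50

    def test_error_free_reads_are_exact_substrings(self, refs):
        reads, truth = simulate_reads(
            refs, self.uniform(refs), n_reads=40, error_rate=0.0, seed=2
        )
        for read in reads:
            ref, s, e = truth.read_footprints[read.read_id]
            assert read.sequence == refs.sequence(ref)[s:e]

    def test_clean_count_is_exact_partition(self, refs):
        reads, _ = simulate_reads(
            refs, self.uniform(refs), n_reads=200, clean_fraction=0.3, seed=3
        )
        assert sum(r.truth_label == "clean" for r in reads) == 60

    def test_deterministic_given_seed(self, refs):
        a, _ = simulate_reads(refs, self.uniform(refs), 30, seed=9, clean_fraction=0.5)
        b, _ = simulate_reads(refs, self.uniform(refs), 30, seed=9, clean_fraction=0.5)
        assert a == b

    def test_source_intervals_restrict_footprints(self, refs):
        intervals = {ref_id: [(200, 400)] for ref_id in refs}
        reads, truth = simulate_reads(
            refs,
            self.uniform(refs),
            n_reads=60,
            seed=5,
            source_intervals=intervals,
        )
        for read in reads:
            _, s, e = truth.read_footprints[read.read_id]
            assert 200 <= s and e <= 400

    def test_read_longer_than_reference_rejected(self, refs):
        with pytest.raises(ConfigError):
            simulate_reads(refs, self.uniform(refs), 10, read_length=5000)

    def test_interval_too_small_for_read_rejected(self, refs):
        intervals = {ref_id: [(0, 40)] for ref_id in refs}
        with pytest.raises(ConfigError):
            simulate_reads(
                refs, self.uniform(refs), 10, source_intervals=intervals
            )


class TestTruthSerialisation:
    def test_json_round_trip(self, tmp_path):
        truth = SyntheticTruth(
            hotspot_intervals={("s1", "r1"): [(10, 60, 700)]},
            read_labels={"q1": "rRNA", "q2": "clean"},
            read_footprints={"q1": ("r1", 10, 86)},
        )
        path = tmp_path / "truth.json"
        truth.to_json(str(path))
        back = SyntheticTruth.from_json(str(path))
        assert back == truth


class TestDefaultScenario:
    def test_bundle_shape_and_determinism(self):
        a = default_scenario(seed=17, n_species=2, n_samples=2, n_reads=100)
        b = default_scenario(seed=17, n_species=2, n_samples=2, n_reads=100)
        assert len(a.references) == 4
        assert sorted(a.tracks_by_sample) == ["sample01", "sample02"]
        assert a.reads == b.reads
        assert [r.sequence for r in a.references.records] == [
            r.sequence for r in b.references.records
        ]

    def test_hotspots_recoverable_by_region_discovery(self):
        bundle = default_scenario(seed=23, n_species=2, n_samples=1, n_reads=50)
        params = DesignParameters()
        for track in bundle.tracks_by_sample["sample01"]:
            planted = bundle.coverage_truth.hotspot_intervals.get(
                ("sample01", track.ref_id), []
            )
            intervals = merge_proximal(
                call_covered_intervals(track, params.min_base_depth),
                params.max_merge_gap,
            )
            regions = score_and_filter(intervals, track, params.min_region_depth)
            assert sorted((r.start, r.end) for r in regions) == sorted(
                (s, e) for s, e, _ in planted
            )
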