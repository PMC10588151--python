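import numpy as np
import pytest
from fractions import Fraction
from hypothesis import given, settings
from hypothesis import strategies as st

from riboprobe.errors import DataError
from riboprobe.models import reverse_complement
from riboprobe.probe_design import antisense
from riboprobe.redundancy_filter import (
    best_strand_identity,
    cluster_redundant,
    exclude_probe_covered,
    pairwise_identity,
    redundancy_components,
)

from conftest import make_region, random_dna
from oracles import semi_global_identity_set

dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


def mutate(rng, seq: str, positions) -> str:
    out = list(seq)
    for p in positions:
        out[p] = "ACGT"[("ACGT".index(out[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGT", 1.0),
            ("ACGTACGTAC", "ACGAACGTAC", 0.9),  # 9 matches / 10 columns
            ("AAAA", "TTTT", 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert pairwise_identity(a, b).identity == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(DataError):
            pairwise_identity("", "ACGT")

    def test_overhangs_do_not_penalise(self):
        core = "ACGTACGTACGTACGTACGT"
        assert pairwise_identity(core, "TTTTT" + core + "GGGGG").identity == 1.0

    @given(dna, dna)
    @settings(max_examples=150, deadline=None)
    def test_symmetry(self, a, b):
        assert pairwise_identity(a, b).identity == pairwise_identity(b, a).identity

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=8),
        st.text(alphabet="ACGT", min_size=1, max_size=8),
    )
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_exhaustive_enumeration(self, a, b):
        _, identities = semi_global_identity_set(a, b)
        res = pairwise_identity(a, b)
        observed = (
            Fraction(res.matches, res.aligned_columns)
            if res.aligned_columns
            else Fraction(0)
        )
        assert observed in identities

    def test_invariants_of_result(self):
        res = pairwise_identity("ACGTACGTAC", "ACGAACGTAC")
        assert 0 <= res.matches <= res.aligned_columns
        assert res.identity == res.matches / res.aligned_columns


class TestClusterRedundant:
    def regions_with(self, seqs, depths=None):
        depths = depths or [600.0] * len(seqs)
        return [
            make_region(
                "r1", i * 1000, i * 1000 + len(s), mean_depth=d, sequence=s
            )
            for i, (s, d) in enumerate(zip(seqs, depths))
        ]

    def test_identical_regions_collapse(self, rng):
        seq = random_dna(rng, 120)
        regions = self.regions_with([seq, seq])
        assert len(cluster_redundant(regions, 0.80)) == 1

    def test_reverse_complement_redundancy_detected(self, rng):
        seq = random_dna(rng, 120)
        regions = self.regions_with([seq, reverse_complement(seq)])
        assert len(cluster_redundant(regions, 0.80)) == 1

    def test_single_linkage_chain_collapses(self, rng):
        b = random_dna(rng, 100)
        pos = rng.choice(100, size=30, replace=False)
        a = mutate(rng, b, pos[:15])  # a~b at 0.85
        c = mutate(rng, b, pos[15:])  # b~c at 0.85, a~c at 0.70
        assert pairwise_identity(a, b).identity >= 0.85
        assert pairwise_identity(b, c).identity >= 0.85
        assert pairwise_identity(a, c).identity < 0.80
        regions = self.regions_with([a, b, c], depths=[600, 900, 700])
        reps = cluster_redundant(regions, 0.80)
        assert len(reps) == 1
        assert reps[0].mean_depth == 900  # deepest region represents the cluster

    def test_components_match_bruteforce_transitive_closure(self, rng):
        base = [random_dna(rng, 80) for _ in range(4)]
        seqs = []
        for b in base:
            seqs.append(b)
            seqs.append(mutate(rng, b, rng.choice(80, size=8, replace=False)))
        order = rng.permutation(len(seqs))
        seqs = [seqs[i] for i in order]
        regions = self.regions_with(seqs)
        comps = redundancy_components(regions, 0.80)
        # brute force: transitive closure over the same edge predicate
        n = len(regions)
        edges = {
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if best_strand_identity(seqs[i], seqs[j]).identity >= 0.80
        }
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for i, j in edges:
            parent[find(i)] = find(j)
        expected = {}
        for i in range(n):
            expected.setdefault(find(i), set()).add(i)
        assert {frozenset(c) for c in comps} == {
            frozenset(c) for c in expected.values()
        }

    def test_representatives_pairwise_below_threshold(self, rng):
        seqs = [random_dna(rng, 90) for _ in range(6)]
        reps = cluster_redundant(self.regions_with(seqs), 0.80)
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                assert (
                    best_strand_identity(reps[i].sequence, reps[j].sequence).identity
                    < 0.80
                )

    def test_survivors_keep_input_order(self, rng):
        seqs = [random_dna(rng, 90) for _ in range(5)]
        regions = self.regions_with(seqs)
        reps = cluster_redundant(regions, 0.80)
        indices = [regions.index(r) for r in reps]
        assert indices == sorted(indices)

    def test_missing_sequence_rejected(self):
        with pytest.raises(DataError):
            cluster_redundant([make_region(sequence=None)], 0.80)


class TestExcludeProbeCovered:
    def region_from(self, seq):
        return make_region("r1", 0, len(seq), sequence=seq)

    def test_exact_probe_target_eliminated(self, rng):
        seq = random_dna(rng, 150)
        probe = antisense(seq[50:100])
        survivors, hits = exclude_probe_covered(
            [self.region_from(seq)], [("p1", probe)], 0.80
        )
        assert survivors == []
        assert hits[0].probe_id == "p1"

    def test_unrelated_probe_keeps_region(self, rng):
        survivors, hits = exclude_probe_covered(
            [self.region_from(random_dna(rng, 150))],
            [("p1", random_dna(rng, 50))],
            0.80,
        )
        assert len(survivors) == 1 and hits == []

    def test_reverse_strand_match_eliminates(self, rng):
        seq = random_dna(rng, 150)
        probe = mutate(rng, seq[40:90], rng.choice(50, size=5, replace=False))
        # probe matches the region's sense strand at 0.9; the antisense probe
        # catalogue orientation is the reverse complement
        survivors, hits = exclude_probe_covered(
            [self.region_from(seq)], [("p1", reverse_complement(probe))], 0.80
        )
        assert survivors == []
        assert hits[0].strand == "-"

    def test_short_fluke_alignment_cannot_eliminate(self, rng):
        seq = random_dna(rng, 150)
        # perfect 10-nt match embedded in an otherwise random 50-nt probe
        probe = random_dna(rng, 20) + seq[60:70] + random_dna(rng, 20)
        survivors, _ = exclude_probe_covered(
            [self.region_from(seq)], [("p1", probe)], 0.80
        )
        assert len(survivors) == 1

    def test_empty_probe_set_warns_and_keeps_all(self, rng, caplog):
        regions = [self.region_from(random_dna(rng, 120))]
        with caplog.at_level("WARNING"):
            survivors, hits = exclude_probe_covered(regions, [], 0.80)
        assert survivors == regions and hits == []
        assert "empty existing probe set" in caplog.text

    def test_adding_probes_is_monotone(self, rng):
        regions = [self.region_from(random_dna(rng, 150)) for _ in range(5)]
        probes = [
            ("p%d" % i, antisense(regions[i].sequence[20:70])) for i in range(4)
        ]
        counts = [
            len(exclude_probe_covered(regions, probes[:k], 0.80)[0])
            for k in range(1, 5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic(self, rng):
        regions = [self.region_from(random_dna(rng, 120)) for _ in range(4)]
        probes = [("p1", antisense(regions[0].sequence[10:60]))]
        first = exclude_probe_covered(regions, probes, 0.80)
        second = exclude_probe_covered(regions, probes, 0.80)
        assert first == second
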