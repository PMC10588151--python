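import numpy as np
import pytest

from riboprobe.models import CoverageTrack, ReferenceRecord, ReferenceSet, Region


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_references():
    return ReferenceSet(
        [
            ReferenceRecord("r1", "ACGTACGTACGTACGTACGT"),  # 20 nt
            ReferenceRecord("r2", "TTTTACGTACGTACGTACGTACGTACGTGGGG"),  # 32 nt
        ]
    )


def make_track(ref_id, depth, sample_id="s1"):
    return CoverageTrack(ref_id=ref_id, sample_id=sample_id, depth=np.asarray(depth))


def make_region(ref_id="r1", start=0, end=10, mean_depth=600.0, sequence=None, samples=("s1",)):
    return Region(
        ref_id=ref_id,
        start=start,
        end=end,
        mean_depth=mean_depth,
        sample_ids=frozenset(samples),
        sequence=sequence,
    )


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
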