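import numpy as np
import pandas as pd
import pytest

from haplopop import Alignment, SampleMetadata, synth


@pytest.fixture
def toy_alignment():
    ids = [f"s{i}" for i in range(6)]
    seqs = ["AAAAA", "AAAAT", "AAAAA", "AATAT", "TTAAA", "TTAAT"]
    return Alignment(ids, seqs)


@pytest.fixture
def toy_metadata(toy_alignment):
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": toy_alignment.ids,
                "location": ["L1", "L1", "L1", "L2", "L3", "L3"],
                "area": ["X", "X", "X", "X", "Y", "Y"],
                "lat": [10.0, 10.0, 10.0, 12.0, 20.0, 20.0],
                "lon": [0.0, 0.0, 0.0, 1.0, 5.0, 5.0],
            }
        )
    )


@pytest.fixture(scope="session")
def small_study():
    """Reduced synthetic survey: 3 areas, 6 locations, 8 samples each."""
    cfg = synth.SimConfig(
        areas=[
            ("A1", ["p1", "p2"], [8, 8]),
            ("A2", ["p3", "p4"], [8, 8]),
            ("A3", ["p5", "p6"], [8, 8]),
        ],
        theta=8.0,
        mig_within=5.0,
        mig_between=0.0,
        expansion=(0.3, 50.0),
        merge_time=2.0,
        seq_length=400,
        seed=11,
    )
    return synth.simulate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """The shipped full-size default scenario (312 samples, 13 locations)."""
    return synth.simulate_study(synth.default_config(seed=1))


def brute_force_differences(seqs):
    """Per-site double-loop pairwise difference count with masking."""
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            c = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in "ACGT" and b in "ACGT" and a != b:
                    c += 1
            d[i, j] = c
    return d
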