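import numpy as np
import pytest

from mitocapture import alignment as A
from mitocapture import simdata
from mitocapture.core_io import encode_seq


@pytest.fixture
def small_ref():
    return A.ReferenceIndex([("c1", 60), ("c2", 40)])


def make_sample(taxon, seq, coverage=None):
    calls = encode_seq(seq)
    if coverage is None:
        coverage = np.full(calls.size, 100)
    return A.SampleConsensus(taxon, calls, np.asarray(coverage))


@pytest.fixture
def clean_dataset():
    """Small dropout-free simulated dataset shared across tests."""
    params = simdata.SimParams(
        n_contigs=3,
        total_ref_len=6000,
        n_taxa=6,
        rng_seed=11,
        dropout_base=0.0,
        indel_rate=0.3,
        mean_branch_len=0.01,
    )
    return simdata.simulate_dataset(params)


@pytest.fixture
def built(clean_dataset):
    cfg = A.CleaningConfig()
    samples = [A.mask_low_coverage(s, cfg) for s in clean_dataset.samples]
    return A.build_alignment(samples, clean_dataset.ref_index, cfg)
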