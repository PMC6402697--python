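import numpy as np
import pytest

from mmctm.containers import CountMatrix
from mmctm.encoding import snv_category_space, sv_category_space


@pytest.fixture(scope="session")
def snv_space():
    return snv_category_space()


@pytest.fixture(scope="session")
def sv_space():
    return sv_category_space()


@pytest.fixture(scope="session")
def toy_reference():
    """A two-contig reference small enough to read by eye."""
    return {
        "chr1": "ACGTACGTACGTACGTACGT",
        "chr2": "TTGACCATGGCATCGATCGA",
    }


def subset_counts(cm: CountMatrix, idx: list[int]) -> CountMatrix:
    return CountMatrix([cm.sample_ids[i] for i in idx], cm.category_space,
                       cm.counts[idx])


@pytest.fixture(scope="session")
def small_corpus(snv_space):
    """A 60-sample, 3-signature SNV Poisson corpus used by several tests."""
    from mmctm.simulate import (SimulationSpec, draw_dirichlet_probs,
                                simulate_counts, synthetic_signatures)

    sigs = synthetic_signatures(3, snv_space, seed=11)
    probs = draw_dirichlet_probs(3, 60, seed=12)
    counts = simulate_counts(
        SimulationSpec([sigs], [probs], [np.full(60, 1500)], seed=13))[0]
    return sigs, probs, counts
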