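import numpy as np
import pytest

from bnbpower import BNBParams, LongCounts, PairedCounts, bnb_rvs


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def paired_counts_small():
    """A fixed 10-pair dataset drawn from BNB(mu=10, gamma=2, phi=1)."""
    return bnb_rvs(BNBParams(10, 2, 1), 10, 42)


@pytest.fixture
def long_counts_small(paired_counts_small):
    return LongCounts.from_paired(paired_counts_small)
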