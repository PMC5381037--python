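import numpy as np
import pytest

from ibsancestry.popstats import DiversityEstimates
from ibsancestry.seqio import PseudoHaploidSeq


@pytest.fixture
def bear_div() -> DiversityEstimates:
    """The polar/brown diversity values used throughout the validation runs."""
    return DiversityEstimates(pi_A=0.000615, pi_B=0.00233, pi_AB=0.003564)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


def seq(name: str, s: str) -> PseudoHaploidSeq:
    return PseudoHaploidSeq.from_string(name, s)


@pytest.fixture
def make_seq():
    return seq
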