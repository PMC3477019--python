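import numpy as np
import pytest

from coregscan.fixtures import example_model
from coregscan.motifs import IUPACMotif, PositionWeightMatrix
from coregscan.seqio import SequenceRecord


@pytest.fixture
def grbox_model():
    """The 4-element anchor model: GRBOX / MZF1-like / EGR1-like / TATA."""
    return example_model()


@pytest.fixture
def wide_gap_model():
    """Same elements with wide gaps (span > 220 nt) for genome fixtures."""
    return example_model([(70, 90), (60, 80), (70, 90)])


@pytest.fixture
def simple_pwm():
    """A 5-position PWM with a sharp consensus TCCCC."""
    f = np.array([
        [0.05, 0.05, 0.05, 0.85],
        [0.04, 0.88, 0.04, 0.04],
        [0.04, 0.88, 0.04, 0.04],
        [0.04, 0.88, 0.04, 0.04],
        [0.04, 0.88, 0.04, 0.04],
    ])
    return PositionWeightMatrix("V$MZF1.01", f)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
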