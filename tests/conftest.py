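import numpy as np
import pytest

from qgramfir import FilterCoefficients, SequenceRecord

#: The worked mono-gram example: sequence AACTCG with window [0.2, 0.1, 0.3, 0.4].
EXAMPLE_SEQ = "AACTCG"
EXAMPLE_TAPS = [0.2, 0.1, 0.3, 0.4]


@pytest.fixture
def example_record() -> SequenceRecord:
    return SequenceRecord("ex", EXAMPLE_SEQ)


@pytest.fixture
def example_coeffs() -> FilterCoefficients:
    return FilterCoefficients(np.array(EXAMPLE_TAPS))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
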