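import numpy as np
import pytest

from catseq import DEFAULT_SCORING, ScoringConstants


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[c] for c in rng.integers(0, 4, size=length))


@pytest.fixture
def constants() -> ScoringConstants:
    return DEFAULT_SCORING


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240307)
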