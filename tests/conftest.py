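import numpy as np
import pytest

from centroscape.synth import _motif_free_seq, _random_codes, decode


def rand_dna(rng: np.random.Generator, n: int, gc: float = 0.36) -> str:
    return decode(_random_codes(rng, n, gc))


def motif_free_dna(rng: np.random.Generator, n: int, gc: float = 0.36) -> str:
    return decode(_motif_free_seq(rng, n, gc))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
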