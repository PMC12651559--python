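import numpy as np
import pytest

from replireset.genome import GenomeMap, ecoli_k12


@pytest.fixture
def toy_genome():
    """10-kb circular genome with oriC at 6 kb and terminus at 1 kb."""
    return GenomeMap(
        length=10_000,
        oric=6_000,
        terminus_window=(800, 1_200),
        loci={"block": 4_500},
    )


@pytest.fixture
def ecoli():
    return ecoli_k12()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
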