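import numpy as np
import pytest

from mobiqc.chimera_sim import random_seq
from mobiqc.core_io import Genome


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_genome(rng):
    """10 kb single-chromosome random genome."""
    return Genome([("chr1", random_seq(10_000, 0.42, rng))])


@pytest.fixture
def two_chrom_genome(rng):
    return Genome(
        [
            ("chr1", random_seq(12_000, 0.42, rng)),
            ("chr2", random_seq(8_000, 0.42, rng)),
        ]
    )
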