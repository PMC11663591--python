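import numpy as np
import pytest

from xomap.genome import arabidopsis_like_genome, default_annotation
from xomap.pipeline import make_marker_scaffold


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def genome():
    return arabidopsis_like_genome()


@pytest.fixture(scope="session")
def annotation(genome):
    return default_annotation(genome)


@pytest.fixture(scope="session")
def markers_50kb(genome):
    return make_marker_scaffold(genome, 50_000)
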