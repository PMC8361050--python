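import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from grntopo.containers import InteractionNetwork
from oracles import random_signed_weights


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_random_network(n, density, rng):
    return InteractionNetwork(
        gene_ids=[f"v{i}" for i in range(n)],
        weights=random_signed_weights(n, density, rng),
    )


@pytest.fixture
def random_network_factory():
    return make_random_network
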