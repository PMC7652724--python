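import numpy as np
import pytest

from funregnet.grn_store import build_network
from funregnet.ortho_transfer import InferredInteraction
from funregnet.synthetic_fixtures import FixtureConfig, generate_fixture


def make_edges(pairs, effect="unknown", species="Anidulans"):
    """Build merged InferredInteraction edges from bare (tf, tg) pairs."""
    return [
        InferredInteraction(tf, tg, frozenset({species}), effect=effect)
        for tf, tg in pairs
    ]


def make_network(pairs):
    return build_network(make_edges(pairs))


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default synthetic input bundle shared across tests."""
    out = tmp_path_factory.mktemp("fixture")
    return generate_fixture(FixtureConfig(seed=11), out)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
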