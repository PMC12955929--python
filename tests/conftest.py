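import numpy as np
import pytest

from specmol.fixtures import make_fixture_table
from specmol.molgraph import Molecule, build_graph
from specmol.network import EncoderConfig, Model


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale architecture used throughout the fast tests."""
    return EncoderConfig(d_model=16, n_heads=2, n_layers=1,
                         transformer_layers=1)


@pytest.fixture(scope="session")
def small_model(small_cfg):
    return Model(small_cfg, 1, ["regression"], seed=0)


@pytest.fixture(scope="session")
def fixture_table():
    return make_fixture_table(seed=0, noise_sd=0.0)


@pytest.fixture()
def graph_of():
    def _build(smiles: str):
        return build_graph(Molecule.from_smiles(smiles))
    return _build


@pytest.fixture(scope="session")
def rng():
    return np.random.Generator(np.random.PCG64(1234))
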