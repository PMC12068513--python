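import numpy as np
import pytest

from symfrag.fixtures import FixtureSpec, TOY_Y6_CONFIG, generate_fixtures
from symfrag.fragment_decomposition import decompose_corpus
from symfrag.mdp_environments import PatentEnvironment, Y6Environment
from symfrag.reward_and_acquisition import ConjugationBandgapOracle


@pytest.fixture(scope="session")
def fixture_corpus():
    """Sixty assembled molecules with known fragment composition."""
    return generate_fixtures(FixtureSpec(n_molecules=60, seed=7))


@pytest.fixture(scope="session")
def toy_env():
    """Enumerable focused grammar (120 terminal molecules)."""
    return Y6Environment(TOY_Y6_CONFIG)


@pytest.fixture(scope="session")
def oracle():
    return ConjugationBandgapOracle()


@pytest.fixture(scope="session")
def patent_pool(fixture_corpus):
    return decompose_corpus([m.smiles for m in fixture_corpus[:30]])


@pytest.fixture(scope="session")
def patent_env(patent_pool):
    return PatentEnvironment(patent_pool, k_clusters=8, seed=0,
                             max_heavy_atoms=60)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
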