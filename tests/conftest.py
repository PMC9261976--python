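import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from shellstrata import datasets
from shellstrata.tree import SpeciesTree

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def metazoa_tree() -> SpeciesTree:
    return datasets.load_metazoa_tree()


@pytest.fixture(scope="session")
def toy_tree() -> SpeciesTree:
    # 6 leaves, fully labeled: ((A,B)AB,((C,D)CD,(E,F)EF)CDEF)R
    return SpeciesTree.from_newick("((A,B)AB,((C,D)CD,(E,F)EF)CDEF)R;")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
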