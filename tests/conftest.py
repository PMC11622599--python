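import numpy as np
import pytest

from chemsa.chem_core import canonicalize
from chemsa.workspace import bundled_drug_smiles, fixture_fragments, fixture_pool


@pytest.fixture(scope="session")
def bundle():
    """All bundled drug-like molecules, canonicalized."""
    return [canonicalize(s) for s in bundled_drug_smiles()]


@pytest.fixture(scope="session")
def pool100():
    return fixture_pool(100, rng_seed=7)


@pytest.fixture(scope="session")
def fragdb200():
    return fixture_fragments(200, rng_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
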