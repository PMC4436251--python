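import numpy as np
import pytest

from betanest import CommunityMatrix, table1_fixture


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20150518)


def random_community(rng, n_sites=8, n_species=12, fill=0.4,
                     no_empty=True) -> CommunityMatrix:
    """Random binary matrix; optionally guarantees no empty sites/species."""
    while True:
        inc = (rng.random((n_sites, n_species)) < fill).astype(int)
        if not no_empty:
            break
        if inc.sum(axis=1).min() > 0 and inc.sum(axis=0).min() > 0:
            break
    return CommunityMatrix(
        tuple(f"s{i}" for i in range(n_sites)),
        tuple(f"sp{j}" for j in range(n_species)), inc)
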