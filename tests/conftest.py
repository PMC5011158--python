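"""Shared fixtures: small molecules, embedded conformers, rng helpers."""

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from flavoqsar.structures_io import read_structures, embed3d

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def _embedded(smiles_line: str, seed: int = 11):
    mol = read_structures(smiles_line)[0]
    return embed3d(mol, seed=seed)


@pytest.fixture(scope="session")
def methane():
    return _embedded("C methane")


@pytest.fixture(scope="session")
def ethanol():
    return _embedded("CCO ethanol")


@pytest.fixture(scope="session")
def water():
    return _embedded("O water")


@pytest.fixture(scope="session")
def benzene():
    return _embedded("c1ccccc1 benzene")


@pytest.fixture(scope="session")
def pyridine():
    return _embedded("c1ccncc1 pyridine")


@pytest.fixture(scope="session")
def quercetin():
    return _embedded(
        "O=C1C(O)=C(c2ccc(O)c(O)c2)Oc2cc(O)cc(O)c21 quercetin")


@pytest.fixture()
def rng():
    return np.random.default_rng(20160804)
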