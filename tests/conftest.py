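import warnings

import numpy as np
import pytest

from prionmc import (Conformation, build_structure, get_peptide, get_topology,
                     make_ideal_helix)


@pytest.fixture(scope="session")
def seq14():
    return get_peptide("109-122")


@pytest.fixture(scope="session")
def seq14_mut():
    return get_peptide("109-122_A117V")


@pytest.fixture(scope="session")
def seq21():
    return get_peptide("106-126")


@pytest.fixture(scope="session")
def topo14(seq14):
    return get_topology(seq14)


@pytest.fixture(scope="session")
def helix14(seq14, topo14):
    conf = Conformation(np.full(14, -57.0), np.full(14, -47.0), topo14.default_chi())
    return build_structure(seq14, conf)


@pytest.fixture(scope="session")
def strand14(seq14, topo14):
    conf = Conformation(np.full(14, -120.0), np.full(14, 130.0), topo14.default_chi())
    return build_structure(seq14, conf)


@pytest.fixture(autouse=True)
def _quiet_tuning_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def random_conformation(topo, rng):
    n = topo.n_residues
    return Conformation(rng.uniform(-180, 180, n), rng.uniform(-180, 180, n),
                        rng.uniform(-180, 180, topo.n_chi))
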