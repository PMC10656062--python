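import numpy as np
import pytest

import nmremu as nm


@pytest.fixture(scope="session")
def methyl():
    """The acetonitrile methyl-group fixture: [13C, 1H, 1H, 1H], J = 136.2 Hz."""
    return nm.fixture_acetonitrile()


@pytest.fixture(scope="session")
def methyl_h(methyl):
    return nm.build_hamiltonian(methyl)


@pytest.fixture(scope="session")
def methyl_obs(methyl):
    return nm.weighted_total_magnetization(methyl)


def random_heteronuclear(n_sites: int, rng: np.random.Generator,
                         j_scale: float = 100.0) -> nm.SpinSystem:
    """A random fully coupled heteronuclear system for property tests."""
    labels = ["1H", "13C", "19F", "31P"]
    sites = tuple(nm.isotope(labels[i % len(labels)]) for i in range(n_sites))
    j = np.zeros((n_sites, n_sites))
    for i in range(n_sites):
        for k in range(i + 1, n_sites):
            j[i, k] = j[k, i] = j_scale * (0.2 + rng.random())
    return nm.SpinSystem(sites, j)


def heteronuclear_pair(j_hz: float) -> nm.SpinSystem:
    j = np.array([[0.0, j_hz], [j_hz, 0.0]])
    return nm.SpinSystem((nm.isotope("13C"), nm.isotope("1H")), j)


def homonuclear_pair(j_hz: float) -> nm.SpinSystem:
    j = np.array([[0.0, j_hz], [j_hz, 0.0]])
    return nm.SpinSystem((nm.isotope("1H"), nm.isotope("1H")), j)
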