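"""Built-in spin systems: the acetonitrile methyl group and synthetic
clustered molecules.

The methyl-group fixture is isotope-labeled acetonitrile's NMR-active core:
one 13C and three 1H with three equal one-bond couplings J = 136.2 Hz and no
H-H couplings.  Its zero-field spectrum has exactly two lines, at J and 2J.

The clustered generator emulates the structure of molecules at the border of
classical simulability: strongly interacting clusters of four to seven spins
weakly bridged to their neighbors.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .spin_system import SpinSystem, isotope

__all__ = ["fixture_acetonitrile", "random_clustered_system", "dipolar_toy_system"]

#: One-bond 13C-1H scalar coupling of the acetonitrile methyl group, Hz.
ACETONITRILE_J_HZ = 136.2


def fixture_acetonitrile() -> SpinSystem:
    """The four-spin methyl group: [13C, 1H, 1H, 1H], J(C,H) = 136.2 Hz."""
    j = np.zeros((4, 4))
    j[0, 1:] = ACETONITRILE_J_HZ
    j[1:, 0] = ACETONITRILE_J_HZ
    sites = (isotope("13C"), isotope("1H"), isotope("1H"), isotope("1H"))
    return SpinSystem(sites, j)


def random_clustered_system(n_clusters: int, cluster_size_range: Tuple[int, int] = (4, 7),
                            intra_j: float = 100.0, inter_j: float = 5.0,
                            seed: Optional[int] = None,
                            max_sites: int = 12) -> SpinSystem:
    """A block-structured random molecule of weakly bridged spin clusters.

    Intra-cluster couplings are dense, drawn around the ``intra_j`` scale;
    adjacent clusters are connected by exactly one weak bridge coupling
    around ``inter_j``.  Isotopes alternate 1H / 13C round-robin so systems
    are heteronuclear.  Deterministic per seed.
    """
    if not inter_j < intra_j:
        raise ValueError("inter-cluster couplings must be weaker than intra-cluster")
    rng = np.random.default_rng(seed)
    lo, hi = cluster_size_range
    if not (4 <= lo <= hi <= 7):
        raise ValueError("cluster sizes must lie in 4..7")
    sizes = rng.integers(lo, hi + 1, size=n_clusters)
    n = int(sizes.sum())
    if n > max_sites:
        raise ValueError(f"{n} spins exceeds the dense-backend cap of {max_sites}; "
                         "reduce cluster count or sizes")
    j = np.zeros((n, n))
    starts = np.concatenate([[0], np.cumsum(sizes)])
    for c in range(n_clusters):
        a, b = starts[c], starts[c + 1]
        for i in range(a, b):
            for k in range(i + 1, b):
                val = intra_j * (0.5 + rng.random())
                j[i, k] = j[k, i] = val
    for c in range(n_clusters - 1):
        # one bridge between a random site of cluster c and of cluster c+1
        i = rng.integers(starts[c], starts[c + 1])
        k = rng.integers(starts[c + 1], starts[c + 2])
        val = inter_j * (0.5 + rng.random())
        j[i, k] = j[k, i] = val
    labels = ["1H", "13C"]
    sites = tuple(isotope(labels[i % 2]) for i in range(n))
    return SpinSystem(sites, j)


def dipolar_toy_system(seed: Optional[int] = None) -> SpinSystem:
    """Three protons at fixed, slightly irregular positions (angstrom).

    A minimal solid-state toy: no scalar couplings, all dynamics from the
    orientation-dependent dipolar interaction.  Used by the powder-average
    machinery and its tests.
    """
    rng = np.random.default_rng(seed)
    coords = np.array([[0.0, 0.0, 0.0],
                       [1.8, 0.1, 0.0],
                       [0.7, 1.6, 0.3]])
    if seed is not None:
        coords = coords + 0.05 * rng.standard_normal(coords.shape)
    sites = (isotope("1H"), isotope("1H"), isotope("1H"))
    return SpinSystem(sites, np.zeros((3, 3)), coords=coords)
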