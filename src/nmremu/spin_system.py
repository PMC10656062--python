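"""Nuclear spin systems and their Hamiltonians.

A spin system is an ordered collection of spin-1/2 nuclei with a symmetric
scalar (J) coupling matrix, optional chemical shifts, and optional Cartesian
site coordinates for through-space dipolar couplings.  Everything downstream
(exact dynamics, circuit emulation, powder averaging) consumes the dense
operator matrices built here.

Units
-----
* J couplings and chemical shifts are given in Hz; Hamiltonians are returned
  in rad/s.
* Gyromagnetic ratios are stored as dimensionless ratios to the proton, so
  magnetization observables come out in units of gamma(1H) ("gamma_ref").
* Coordinates are in angstroms; dipolar coupling constants use the absolute
  proton gyromagnetic ratio internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GAMMA_H",
    "ISOTOPE_GAMMA_RATIOS",
    "MAX_SITES",
    "Isotope",
    "SpinSystem",
    "OperatorMatrix",
    "isotope",
    "spin_operator",
    "build_hamiltonian",
    "build_dipolar_hamiltonian",
    "weighted_total_magnetization",
    "magnetization_weights",
    "positive_magnetization_states",
    "rotate_vectors",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1 (absolute scale for dipolar terms).
GAMMA_H = 2.6752218744e8

#: Gyromagnetic ratios relative to 1H (NMR frequency ratios).  Only
#: positive-gamma spin-1/2 nuclei are included.
ISOTOPE_GAMMA_RATIOS = {
    "1H": 1.0,
    "13C": 0.25145020,
    "19F": 0.94094011,
    "31P": 0.40480742,
}

#: Hard cap on dense-matrix system size (2^12 = 4096 dimensional).
MAX_SITES = 12

# Reduced Planck constant (J s) and vacuum permeability over 4 pi (T m/A ...)
_HBAR = 1.054571817e-34
_MU0_OVER_4PI = 1.0e-7

_PAULI = {
    "x": np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex),
    "y": np.array([[0.0, -1.0j], [1.0j, 0.0]], dtype=complex),
    "z": np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex),
}


@dataclass(frozen=True)
class Isotope:
    """A spin-1/2 nuclear isotope.

    ``gamma`` is the gyromagnetic ratio relative to 1H (dimensionless,
    positive); ``spin`` is restricted to 1/2.
    """

    label: str
    gamma: float
    spin: float = 0.5

    def __post_init__(self) -> None:
        if self.spin != 0.5:
            raise ValueError(f"only spin-1/2 nuclei are supported, got spin={self.spin}")
        if not self.gamma > 0:
            raise ValueError(f"gamma ratio must be positive, got {self.gamma}")


def isotope(label: str) -> Isotope:
    """Look up an :class:`Isotope` from the built-in table by label."""
    try:
        return Isotope(label, ISOTOPE_GAMMA_RATIOS[label])
    except KeyError:
        known = ", ".join(sorted(ISOTOPE_GAMMA_RATIOS))
        raise KeyError(f"unknown isotope {label!r}; known isotopes: {known}") from None


@dataclass(frozen=True)
class OperatorMatrix:
    """Hermitian operator on the 2^N-dimensional computational product basis.

    ``units`` tags the physical scale: ``"rad/s"`` for Hamiltonians,
    ``"gamma_ref"`` for magnetization observables.
    """

    data: np.ndarray
    units: str = "rad/s"

    def __post_init__(self) -> None:
        a = np.asarray(self.data, dtype=complex)
        object.__setattr__(self, "data", a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"operator must be square, got shape {a.shape}")
        n = a.shape[0]
        if n & (n - 1) != 0:
            raise ValueError(f"dimension {n} is not a power of 2")
        scale = max(np.abs(a).max(), 1.0)
        if np.abs(a - a.conj().T).max() > 1e-12 * scale:
            raise ValueError("operator is not Hermitian to 1e-12 relative tolerance")

    @property
    def dim(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return int(np.log2(self.dim))


def _as_square_sym(j: Sequence, n: int, name: str) -> np.ndarray:
    a = np.asarray(j, dtype=float)
    if a.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}, got shape {a.shape}")
    if not np.allclose(a, a.T, rtol=0, atol=1e-12 * max(1.0, np.abs(a).max())):
        i, k = np.unravel_index(np.argmax(np.abs(a - a.T)), a.shape)
        raise ValueError(f"{name} must be symmetric; entry ({i},{k}) != ({k},{i})")
    if np.abs(np.diag(a)).max(initial=0.0) > 0:
        i = int(np.argmax(np.abs(np.diag(a))))
        raise ValueError(f"{name} must have zero diagonal; entry ({i},{i}) is {a[i, i]}")
    return a


@dataclass(frozen=True)
class SpinSystem:
    """A molecule's NMR-active nuclei: isotopes, J couplings, shifts, geometry.

    Parameters
    ----------
    sites : sequence of Isotope
        Ordered nuclear sites (site ``i`` maps to qubit ``i``).
    j_hz : (N, N) array
        Symmetric scalar-coupling matrix in Hz with zero diagonal.
    shifts_hz : (N,) array, optional
        Chemical shifts in Hz (ignored in zero-field mode).  Default zeros.
    coords : (N, 3) array, optional
        Site positions in angstrom, required for dipolar couplings.
    orientation : (4,) array, optional
        Unit quaternion (w, x, y, z) rotating the coordinates; identity by
        default.
    """

    sites: tuple
    j_hz: np.ndarray
    shifts_hz: Optional[np.ndarray] = None
    coords: Optional[np.ndarray] = None
    orientation: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        sites = tuple(self.sites)
        if not sites:
            raise ValueError("spin system needs at least one site")
        if len(sites) > MAX_SITES:
            raise ValueError(f"at most {MAX_SITES} sites supported, got {len(sites)}")
        for s in sites:
            if not isinstance(s, Isotope):
                raise TypeError(f"sites must be Isotope instances, got {type(s)}")
        object.__setattr__(self, "sites", sites)
        n = len(sites)
        object.__setattr__(self, "j_hz", _as_square_sym(self.j_hz, n, "J matrix"))
        shifts = np.zeros(n) if self.shifts_hz is None else np.asarray(self.shifts_hz, float)
        if shifts.shape != (n,):
            raise ValueError(f"shifts must have length {n}, got shape {shifts.shape}")
        object.__setattr__(self, "shifts_hz", shifts)
        if self.coords is not None:
            c = np.asarray(self.coords, dtype=float)
            if c.shape != (n, 3):
                raise ValueError(f"coords must be {n}x3, got shape {c.shape}")
            d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() <= 1e-9:
                i, k = np.unravel_index(np.argmin(d), d.shape)
                raise ValueError(f"sites {i} and {k} are coincident")
            object.__setattr__(self, "coords", c)
        if self.orientation is not None:
            q = np.asarray(self.orientation, dtype=float)
            if q.shape != (4,) or not np.isclose(np.linalg.norm(q), 1.0, atol=1e-9):
                raise ValueError("orientation must be a unit quaternion (w, x, y, z)")
            object.__setattr__(self, "orientation", q)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def gammas(self) -> np.ndarray:
        """Gyromagnetic ratios relative to 1H, one per site."""
        return np.array([s.gamma for s in self.sites])

    def replace_orientation(self, quaternion: np.ndarray) -> "SpinSystem":
        return SpinSystem(self.sites, self.j_hz, self.shifts_hz, self.coords, quaternion)


def spin_operator(n_sites: int, site: int, axis: str) -> OperatorMatrix:
    """Single-site spin operator ``S_site^axis`` embedded in the full space.

    Returns ``I (x) ... (x) sigma_axis/2 (x) ... (x) I`` with site 0 as the
    leftmost (most significant) tensor factor; eigenvalues are +-1/2.
    """
    if n_sites < 1 or n_sites > MAX_SITES:
        raise ValueError(f"n_sites must be in [1, {MAX_SITES}], got {n_sites}")
    if not 0 <= site < n_sites:
        raise ValueError(f"site {site} out of range for {n_sites} sites")
    if axis not in _PAULI:
        raise ValueError(f"axis must be one of x, y, z, got {axis!r}")
    op = np.array([[1.0]], dtype=complex)
    for i in range(n_sites):
        factor = 0.5 * _PAULI[axis] if i == site else np.eye(2, dtype=complex)
        op = np.kron(op, factor)
    return OperatorMatrix(op, units="gamma_ref")


def _pair_coupling_matrix(n: int, i: int, j: int) -> np.ndarray:
    """Dense matrix of S_i . S_j (scalar product of two site spins)."""
    out = np.zeros((2**n, 2**n), dtype=complex)
    for ax in "xyz":
        out += spin_operator(n, i, ax).data @ spin_operator(n, j, ax).data
    return out


def build_hamiltonian(system: SpinSystem, mode: str = "zero_field") -> OperatorMatrix:
    """Scalar-coupling (+ optional chemical shift) Hamiltonian in rad/s.

    ``H = sum_{i<j} 2 pi J_ij S_i . S_j  [+ sum_i 2 pi shift_i S_i^x]``

    The pair sum runs over ``i < j`` so each physical coupling is counted
    once.  ``mode="zero_field"`` drops the shift term entirely;
    ``mode="high_field"`` includes it, on the x axis.
    """
    if mode not in ("zero_field", "high_field"):
        raise ValueError(f"mode must be 'zero_field' or 'high_field', got {mode!r}")
    n = system.n_sites
    h = np.zeros((2**n, 2**n), dtype=complex)
    for i in range(n):
        for j in range(i + 1, n):
            if system.j_hz[i, j] != 0.0:
                h += 2 * np.pi * system.j_hz[i, j] * _pair_coupling_matrix(n, i, j)
    if mode == "high_field":
        for i in range(n):
            if system.shifts_hz[i] != 0.0:
                h += 2 * np.pi * system.shifts_hz[i] * spin_operator(n, i, "x").data
    return OperatorMatrix(h, units="rad/s")


def rotate_vectors(vectors: np.ndarray, quaternion: Optional[np.ndarray]) -> np.ndarray:
    """Rotate row vectors by a unit quaternion (w, x, y, z)."""
    if quaternion is None:
        return np.asarray(vectors, dtype=float)
    from scipy.spatial.transform import Rotation

    w, x, y, z = quaternion
    rot = Rotation.from_quat([x, y, z, w])  # scipy uses (x, y, z, w)
    return rot.apply(np.asarray(vectors, dtype=float))


def dipolar_coupling_rad_s(gamma_i: float, gamma_j: float, r_angstrom: float) -> float:
    """Dipolar coupling constant b_ij = mu0 gamma_i gamma_j hbar / (4 pi r^3).

    Gammas are ratios to 1H; the result is in rad/s.
    """
    r_m = r_angstrom * 1e-10
    return _MU0_OVER_4PI * (gamma_i * GAMMA_H) * (gamma_j * GAMMA_H) * _HBAR / r_m**3


def build_dipolar_hamiltonian(system: SpinSystem) -> OperatorMatrix:
    """Full (untruncated) dipolar Hamiltonian, rad/s.

    ``H_D = sum_{i<j} b_ij [ S_i.S_j - 3 (S_i.e_ij)(S_j.e_ij) ]`` with
    ``e_ij`` the unit inter-site vector after applying the system's
    orientation quaternion.  The untruncated form is appropriate at zero
    field, where no quantization axis is singled out.
    """
    if system.coords is None:
        raise ValueError("dipolar Hamiltonian requires site coordinates")
    n = system.n_sites
    coords = rotate_vectors(system.coords, system.orientation)
    gammas = system.gammas
    dim = 2**n
    h = np.zeros((dim, dim), dtype=complex)
    ops = {(i, ax): spin_operator(n, i, ax).data for i in range(n) for ax in "xyz"}
    for i in range(n):
        for j in range(i + 1, n):
            rvec = coords[j] - coords[i]
            r = np.linalg.norm(rvec)
            e = rvec / r
            b = dipolar_coupling_rad_s(gammas[i], gammas[j], r)
            si_dot_sj = sum(ops[(i, ax)] @ ops[(j, ax)] for ax in "xyz")
            si_e = sum(e[k] * ops[(i, ax)] for k, ax in enumerate("xyz"))
            sj_e = sum(e[k] * ops[(j, ax)] for k, ax in enumerate("xyz"))
            h += b * (si_dot_sj - 3.0 * (si_e @ sj_e))
    return OperatorMatrix(h, units="rad/s")


def magnetization_weights(system: SpinSystem) -> np.ndarray:
    """Diagonal of the gamma-weighted total z magnetization, gamma(1H) units.

    Entry ``b`` is ``m_b = sum_i gamma_i * (+1/2 if bit i of b is 0 else -1/2)``
    with site 0 the most significant bit (bit value 0 = spin up).
    """
    n = system.n_sites
    weights = np.zeros(2**n)
    for i, g in enumerate(system.gammas):
        bit = (np.arange(2**n) >> (n - 1 - i)) & 1
        weights += g * (0.5 - bit)
    return weights


def weighted_total_magnetization(system: SpinSystem) -> OperatorMatrix:
    """Observable ``sum_i gamma_i S_i^z`` as a diagonal matrix (gamma_ref units)."""
    return OperatorMatrix(np.diag(magnetization_weights(system)).astype(complex),
                          units="gamma_ref")


def positive_magnetization_states(system: SpinSystem) -> list:
    """Computational basis states with strictly positive magnetization.

    Returns ``(basis_index, weight)`` pairs ordered by descending weight,
    ties broken by ascending index.  These are the initial states of the
    basis-state FID estimator.
    """
    weights = magnetization_weights(system)
    # strict positivity; tiny tolerance guards against float cancellation of
    # gamma ratios that should sum to exactly zero
    idx = np.nonzero(weights > 1e-12)[0]
    order = sorted(idx, key=lambda b: (-weights[b], b))
    return [(int(b), float(weights[b])) for b in order]
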