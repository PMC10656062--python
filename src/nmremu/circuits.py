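"""Clustered product-formula circuits with damping-noise emulation.

Time evolution under the spin Hamiltonian is compiled into a first-order
product formula over a user-chosen partition of the sites into clusters:
each step evolves every intra-cluster Hamiltonian exactly (one
``cluster-block`` gate per cluster) and then applies one two-qubit
``pair-exp`` gate per nonzero inter-cluster coupling.  With every site in
its own cluster this is plain first-order Trotterization.

Circuits are emulated as density matrices.  After each two-qubit gate a
single-qubit amplitude-damping and phase-damping channel acts on every qubit
the gate touched; k-qubit cluster blocks are charged ``cost`` two-qubit-gate
equivalents through a configurable cost model, and the channel is applied
``cost`` times (composed in closed form, which is exact for these commuting
diagonal channels).  Circuit depth is measured as the number of arbitrarily
connected two-qubit gates, the cost unit of the resource estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.linalg import expm

from .spin_system import SpinSystem, build_hamiltonian, magnetization_weights, \
    positive_magnetization_states

__all__ = [
    "Gate",
    "Circuit",
    "NoiseModel",
    "trotter_circuit",
    "two_qubit_depth",
    "cluster_block_cost",
    "run_circuit",
    "circuit_unitary",
    "emulated_fid_point",
    "bhattacharyya",
]


@dataclass(frozen=True)
class Gate:
    """A unitary gate on an ordered tuple of qubits.

    ``meta`` may carry bookkeeping such as the number of couplings inside a
    cluster block (used by the "couplings" cost model).
    """

    qubits: Tuple[int, ...]
    unitary: np.ndarray
    tag: str = "gate"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        q = tuple(int(x) for x in self.qubits)
        if len(set(q)) != len(q):
            raise ValueError(f"repeated qubit in gate: {q}")
        u = np.asarray(self.unitary, dtype=complex)
        d = 2 ** len(q)
        if u.shape != (d, d):
            raise ValueError(f"unitary shape {u.shape} does not match {len(q)} qubits")
        if np.abs(u.conj().T @ u - np.eye(d)).max() > 1e-12 * max(1.0, np.abs(u).max()):
            raise ValueError("gate matrix is not unitary to 1e-12")
        object.__setattr__(self, "qubits", q)
        object.__setattr__(self, "unitary", u)

    @property
    def n_qubits(self) -> int:
        return len(self.qubits)


@dataclass(frozen=True)
class Circuit:
    """An ordered list of gates over ``n_qubits`` qubits."""

    gates: Tuple[Gate, ...]
    n_qubits: int

    def __post_init__(self) -> None:
        gates = tuple(self.gates)
        for g in gates:
            if max(g.qubits, default=-1) >= self.n_qubits:
                raise ValueError(f"gate on qubits {g.qubits} exceeds n_qubits={self.n_qubits}")
        object.__setattr__(self, "gates", gates)


@dataclass(frozen=True)
class NoiseModel:
    """Per-two-qubit-gate damping: amplitude (``p_amp``) and phase (``p_phase``).

    Both parameters are dimensionless Kraus probabilities in [0, 1], applied
    to every qubit a gate touches, once per two-qubit-gate equivalent.
    """

    p_amp: float = 0.0
    p_phase: float = 0.0

    def __post_init__(self) -> None:
        for name, p in (("p_amp", self.p_amp), ("p_phase", self.p_phase)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")

    @property
    def is_noiseless(self) -> bool:
        return self.p_amp == 0.0 and self.p_phase == 0.0

    def composed(self, n: int) -> "NoiseModel":
        """The exact single-channel equivalent of n successive applications.

        Amplitude and phase damping are both diagonal channels on a qubit, so
        their n-fold composition is again an amplitude+phase damping channel
        with p -> 1-(1-p)^n and (1-2q) -> (1-2q)^n.
        """
        p = 1.0 - (1.0 - self.p_amp) ** n
        q = 0.5 * (1.0 - (1.0 - 2.0 * self.p_phase) ** n)
        return NoiseModel(p, q)


# ---------------------------------------------------------------------------
# circuit construction

def _subsystem(system: SpinSystem, sites: Sequence[int]) -> SpinSystem:
    sites = list(sites)
    return SpinSystem(
        tuple(system.sites[i] for i in sites),
        system.j_hz[np.ix_(sites, sites)],
        system.shifts_hz[sites],
    )


def _pair_exp_unitary(j_hz: float, tau: float) -> np.ndarray:
    """exp(-i 2 pi J tau S_i . S_j) on two qubits (4x4)."""
    sdots = np.zeros((4, 4), dtype=complex)
    half = {
        "x": 0.5 * np.array([[0, 1], [1, 0]], dtype=complex),
        "y": 0.5 * np.array([[0, -1j], [1j, 0]], dtype=complex),
        "z": 0.5 * np.array([[1, 0], [0, -1]], dtype=complex),
    }
    for ax in "xyz":
        sdots += np.kron(half[ax], half[ax])
    return expm(-1j * 2 * np.pi * j_hz * tau * sdots)


def _validate_partition(n: int, clusters: Sequence[Sequence[int]]) -> List[Tuple[int, ...]]:
    flat: List[int] = []
    out: List[Tuple[int, ...]] = []
    for c in clusters:
        c = tuple(sorted(int(x) for x in c))
        if len(c) > 7:
            raise ValueError(f"cluster {c} exceeds the maximum size of 7")
        flat.extend(c)
        out.append(c)
    if sorted(flat) != list(range(n)):
        raise ValueError(f"clusters {clusters} are not a partition of 0..{n-1}")
    return out


def trotter_circuit(system: SpinSystem, t: float, n_steps: int,
                    clusters: Optional[Sequence[Sequence[int]]] = None,
                    mode: str = "zero_field") -> Circuit:
    """Clustered first-order product-formula circuit for exp(-i H t).

    One step evolves each intra-cluster Hamiltonian exactly for
    tau = t / n_steps, then applies one pair-exponential per nonzero
    inter-cluster coupling; the step is repeated ``n_steps`` times.  With
    singleton clusters this reduces to plain first-order Trotter with one
    two-qubit gate per coupling per step.
    """
    n = system.n_sites
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if clusters is None:
        clusters = [(i,) for i in range(n)]
    clusters = _validate_partition(n, clusters)
    tau = t / n_steps
    if tau <= 0:
        raise ValueError(f"step duration must be positive, got t={t}, n_steps={n_steps}")

    site_cluster = {}
    for ci, c in enumerate(clusters):
        for s in c:
            site_cluster[s] = ci

    step_gates: List[Gate] = []
    for c in clusters:
        if len(c) == 1:
            # a lone site only evolves under its shift term (if any)
            if mode == "high_field" and system.shifts_hz[c[0]] != 0.0:
                sub = _subsystem(system, c)
                h = build_hamiltonian(sub, mode=mode).data
                step_gates.append(Gate(c, expm(-1j * h * tau), tag="shift"))
            continue
        sub = _subsystem(system, c)
        h = build_hamiltonian(sub, mode=mode).data
        n_couplings = int(np.count_nonzero(np.triu(sub.j_hz, 1)))
        step_gates.append(Gate(c, expm(-1j * h * tau), tag="cluster-block",
                               meta={"n_couplings": n_couplings}))
    for i in range(n):
        for j in range(i + 1, n):
            if site_cluster[i] != site_cluster[j] and system.j_hz[i, j] != 0.0:
                step_gates.append(Gate((i, j), _pair_exp_unitary(system.j_hz[i, j], tau),
                                       tag="pair-exp"))
    return Circuit(tuple(step_gates) * n_steps, n_qubits=n)


def cluster_block_cost(k: int) -> int:
    """Generic two-qubit-gate cost of an arbitrary k-qubit unitary.

    The parameter-counting lower bound ceil((4^k - 3k - 1)/4); 1- and 2-qubit
    gates cost 0 and 1 respectively.
    """
    if k <= 1:
        return 0
    if k == 2:
        return 1
    return math.ceil((4**k - 3 * k - 1) / 4)


def _gate_cost(gate: Gate, cluster_cost: Union[str, Callable[[Gate], int]]) -> int:
    if callable(cluster_cost):
        return int(cluster_cost(gate))
    if gate.n_qubits <= 1:
        return 0
    if gate.n_qubits == 2:
        return 1
    if cluster_cost == "generic":
        return cluster_block_cost(gate.n_qubits)
    if cluster_cost == "couplings":
        try:
            return int(gate.meta["n_couplings"])
        except KeyError:
            raise ValueError(f"gate {gate.tag!r} has no coupling count; "
                             "use the 'generic' cost model") from None
    raise ValueError(f"unknown cluster cost model {cluster_cost!r}")


def two_qubit_depth(circuit: Circuit,
                    cluster_cost: Union[str, Callable[[Gate], int]] = "generic") -> int:
    """Number of (arbitrarily connected) two-qubit gates in the circuit.

    Cluster blocks on k > 2 qubits are charged via ``cluster_cost``:
    ``"generic"`` (default, the parameter-counting bound), ``"couplings"``
    (one gate per intra-cluster coupling) or a callable on the gate.
    """
    return sum(_gate_cost(g, cluster_cost) for g in circuit.gates)


# ---------------------------------------------------------------------------
# density-matrix propagation

def _apply_unitary_rho(rho: np.ndarray, u: np.ndarray, qubits: Tuple[int, ...],
                       n: int) -> np.ndarray:
    k = len(qubits)
    t = rho.reshape((2,) * (2 * n))
    ut = u.reshape((2,) * (2 * k))
    t = np.tensordot(ut, t, axes=(list(range(k, 2 * k)), list(qubits)))
    t = np.moveaxis(t, range(k), qubits)
    uc = np.conj(ut)
    right = [n + q for q in qubits]
    t = np.tensordot(uc, t, axes=(list(range(k, 2 * k)), right))
    t = np.moveaxis(t, range(k), right)
    return t.reshape(2**n, 2**n)


def _apply_kraus_qubit(rho: np.ndarray, kraus: Sequence[np.ndarray], qubit: int,
                       n: int) -> np.ndarray:
    out = np.zeros_like(rho)
    for k in kraus:
        out += _apply_unitary_rho(rho, k, (qubit,), n)
    return out


def _damping_kraus(noise: NoiseModel) -> List[np.ndarray]:
    p, q = noise.p_amp, noise.p_phase
    amp = [np.array([[1, 0], [0, np.sqrt(1 - p)]], dtype=complex),
           np.array([[0, np.sqrt(p)], [0, 0]], dtype=complex)]
    phase = [np.sqrt(1 - q) * np.eye(2, dtype=complex),
             np.sqrt(q) * np.diag([1.0, -1.0]).astype(complex)]
    # compose: apply phase then amplitude (they commute on a single qubit)
    return [a @ ph for a in amp for ph in phase]


def run_circuit(circuit: Circuit, initial_basis_state: int, noise: NoiseModel,
                cluster_cost: Union[str, Callable[[Gate], int]] = "generic") -> np.ndarray:
    """Propagate a computational basis state through the noisy circuit.

    Returns the diagonal of the final density matrix — the outcome
    distribution over the 2^n computational basis states.  After every gate
    of nonzero two-qubit cost, the damping channel acts on each touched qubit
    ``cost`` times (applied as the exact composed channel).
    """
    n = circuit.n_qubits
    dim = 2**n
    if not 0 <= initial_basis_state < dim:
        raise ValueError(f"initial state {initial_basis_state} out of range for {n} qubits")
    rho = np.zeros((dim, dim), dtype=complex)
    rho[initial_basis_state, initial_basis_state] = 1.0
    kraus_cache: dict = {}
    for gate in circuit.gates:
        rho = _apply_unitary_rho(rho, gate.unitary, gate.qubits, n)
        if noise.is_noiseless:
            continue
        cost = _gate_cost(gate, cluster_cost)
        if cost == 0:
            continue
        if cost not in kraus_cache:
            kraus_cache[cost] = _damping_kraus(noise.composed(cost))
        kraus = kraus_cache[cost]
        for qb in gate.qubits:
            rho = _apply_kraus_qubit(rho, kraus, qb, n)
    probs = np.real(np.diag(rho))
    total = probs.sum()
    if abs(total - 1.0) > 1e-10:
        raise RuntimeError(f"channel is not trace preserving: trace={total!r}")
    return np.clip(probs, 0.0, None) / total


def circuit_unitary(circuit: Circuit) -> np.ndarray:
    """Compose the circuit's gates into a full 2^n x 2^n unitary."""
    n = circuit.n_qubits
    dim = 2**n
    u = np.eye(dim, dtype=complex)
    for gate in circuit.gates:
        # apply the gate to each column (treat u as a stack of kets)
        k = len(gate.qubits)
        t = u.reshape((2,) * n + (dim,))
        gt = gate.unitary.reshape((2,) * (2 * k))
        t = np.tensordot(gt, t, axes=(list(range(k, 2 * k)), list(gate.qubits)))
        t = np.moveaxis(t, range(k), gate.qubits)
        u = t.reshape(dim, dim)
    return u


# ---------------------------------------------------------------------------
# FID estimation from circuits

def emulated_fid_point(system: SpinSystem, t: float, n_steps: int,
                       clusters: Optional[Sequence[Sequence[int]]],
                       noise: NoiseModel, shots: Optional[int],
                       seed=None,
                       cluster_cost: Union[str, Callable[[Gate], int]] = "generic",
                       ) -> Tuple[float, float]:
    """One FID sample from the noisy circuit emulation.

    For each positive-magnetization initial basis state the circuit for
    exp(-i H t) is run, ``shots`` outcomes are sampled, and the empirical
    mean magnetization is combined with the basis-state weights; the result
    is normalized by its exact t = 0 value (sum of squared weights), so a
    noiseless, infinite-shot run reproduces the exact normalized FID up to
    Trotter error.  ``shots=None`` uses the exact outcome distribution.
    Returns ``(estimate, standard_error)``; deterministic given ``seed``.
    """
    if shots is not None and shots < 1:
        raise ValueError(f"shots must be >= 1, got {shots}")
    weights = magnetization_weights(system)
    states = positive_magnetization_states(system)
    raw_t0 = sum(m**2 for _, m in states)
    if t == 0:
        circuit = Circuit((), n_qubits=system.n_sites)
    else:
        circuit = trotter_circuit(system, t, n_steps, clusters)
    rng = np.random.default_rng(seed)
    raw = 0.0
    var_raw = 0.0
    for idx, m_n in states:
        probs = run_circuit(circuit, idx, noise, cluster_cost=cluster_cost)
        mean_exact = float(probs @ weights)
        var_exact = float(probs @ (weights - mean_exact) ** 2)
        if shots is None:
            mean, var_mean = mean_exact, 0.0
        else:
            counts = rng.multinomial(shots, probs)
            mean = float(counts @ weights) / shots
            # plug-in variance of the sample mean
            var_mean = float(counts @ (weights - mean) ** 2) / shots / max(shots - 1, 1)
        raw += m_n * mean
        var_raw += m_n**2 * var_mean
    return raw / raw_t0, float(np.sqrt(var_raw)) / raw_t0


def bhattacharyya(p: np.ndarray, q: np.ndarray, squared: bool = False) -> float:
    """Bhattacharyya coefficient BC = sum_i sqrt(p_i q_i) of two distributions.

    BC upper-bounds the fidelity of the underlying quantum states as
    estimated from measured outcome distributions; ``squared`` returns BC^2.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    if (p < -1e-15).any() or (q < -1e-15).any():
        raise ValueError("distributions must be nonnegative")
    bc = float(np.sqrt(np.clip(p, 0, None) * np.clip(q, 0, None)).sum())
    return bc**2 if squared else bc
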