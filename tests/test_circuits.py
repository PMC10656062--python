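"""Product-formula compilation, noisy density-matrix emulation, fidelity scores."""

import numpy as np
import pytest
from scipy.linalg import expm

import nmremu as nm

from conftest import heteronuclear_pair, random_heteronuclear


class TestTrotterCircuit:
    def test_single_cluster_is_exact(self):
        system = heteronuclear_pair(136.2)
        h = nm.build_hamiltonian(system)
        t = 0.013
        circ = nm.trotter_circuit(system, t, 1, clusters=[(0, 1)])
        assert len(circ.gates) == 1
        assert np.abs(nm.circuit_unitary(circ) - expm(-1j * h.data * t)).max() < 1e-10

    def test_singleton_gate_count(self, methyl):
        # 3 couplings x s steps
        for s in (1, 4, 10):
            circ = nm.trotter_circuit(methyl, 0.01, s)
            assert sum(g.tag == "pair-exp" for g in circ.gates) == 3 * s

    def test_commuting_terms_exact_for_any_steps(self):
        # disjoint coupled pairs: the pair terms commute, so one step is exact
        j = np.zeros((4, 4))
        j[0, 1] = j[1, 0] = 50.0
        j[2, 3] = j[3, 2] = 120.0
        sites = tuple(nm.isotope(l) for l in ("1H", "13C", "1H", "13C"))
        system = nm.SpinSystem(sites, j)
        h = nm.build_hamiltonian(system)
        t = 0.004
        u_exact = expm(-1j * h.data * t)
        circ = nm.trotter_circuit(system, t, 1)
        assert np.abs(nm.circuit_unitary(circ) - u_exact).max() < 1e-10

    def test_invalid_partition_rejected(self, methyl):
        with pytest.raises(ValueError, match="partition"):
            nm.trotter_circuit(methyl, 0.01, 1, clusters=[(0, 1), (1, 2, 3)])

    def test_nonpositive_time_rejected(self, methyl):
        with pytest.raises(ValueError):
            nm.trotter_circuit(methyl, 0.0, 1)

    def test_first_order_convergence_slope(self):
        # ||U_circuit - U_exact|| ~ 1/n_steps on random systems
        rng = np.random.default_rng(7)
        for n_sites in (3, 4):
            system = random_heteronuclear(n_sites, rng)
            h = nm.build_hamiltonian(system)
            t = 0.005
            u_exact = expm(-1j * h.data * t)
            steps = np.array([64, 128, 256, 512])
            errs = []
            for s in steps:
                u = nm.circuit_unitary(nm.trotter_circuit(system, t, int(s)))
                errs.append(np.linalg.norm(u - u_exact, 2))
            slope = np.polyfit(np.log(steps), np.log(errs), 1)[0]
            assert abs(slope + 1.0) < 0.15


class TestDepthCounting:
    def test_empty_circuit(self):
        assert nm.two_qubit_depth(nm.Circuit((), 4)) == 0

    def test_methyl_singleton_ten_steps(self, methyl):
        circ = nm.trotter_circuit(methyl, 0.1, 10)
        assert nm.two_qubit_depth(circ) == 30

    def test_generic_cluster_block_cost(self):
        # parameter-counting bound ceil((4^k - 3k - 1)/4)
        assert nm.cluster_block_cost(2) == 1
        assert nm.cluster_block_cost(3) == 14  # ceil(54/4)
        assert nm.cluster_block_cost(4) == 61

    def test_couplings_cost_model(self, methyl):
        circ = nm.trotter_circuit(methyl, 0.1, 1, clusters=[(0, 1, 2, 3)])
        assert nm.two_qubit_depth(circ) == 61
        assert nm.two_qubit_depth(circ, "couplings") == 3


class TestRunCircuit:
    def test_noiseless_matches_unitary(self, methyl):
        circ = nm.trotter_circuit(methyl, 0.01, 2)
        u = nm.circuit_unitary(circ)
        for init in (0, 5, 15):
            probs = nm.run_circuit(circ, init, nm.NoiseModel(0, 0))
            assert np.abs(probs - np.abs(u[:, init]) ** 2).max() < 1e-12

    def test_full_amplitude_damping_decays_to_ground(self):
        # identity two-qubit gate with p_amp = 1 empties the touched qubits
        gate = nm.Gate((0, 1), np.eye(4), tag="idle")
        circ = nm.Circuit((gate,), n_qubits=2)
        probs = nm.run_circuit(circ, 3, nm.NoiseModel(p_amp=1.0, p_phase=0.0))
        assert np.allclose(probs, [1.0, 0.0, 0.0, 0.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_trace_preserved_under_random_noise(self, seed):
        rng = np.random.default_rng(seed)
        system = random_heteronuclear(3, rng)
        circ = nm.trotter_circuit(system, 0.02, 3)
        noise = nm.NoiseModel(rng.uniform(0, 0.3), rng.uniform(0, 0.3))
        probs = nm.run_circuit(circ, int(rng.integers(0, 8)), noise)
        assert abs(probs.sum() - 1.0) < 1e-10

    def test_state_out_of_range(self, methyl):
        circ = nm.trotter_circuit(methyl, 0.01, 1)
        with pytest.raises(ValueError, match="out of range"):
            nm.run_circuit(circ, 16, nm.NoiseModel(0, 0))

    def test_composed_channel_equals_repeated_application(self):
        # the closed-form composition used for cluster-block charging is exact
        noise = nm.NoiseModel(0.02, 0.07)
        gate = nm.Gate((0,), np.eye(2), tag="idle")
        rho = np.array([[0.3, 0.4], [0.4, 0.7]], dtype=complex)
        from nmremu.circuits import _apply_kraus_qubit, _damping_kraus
        repeated = rho.copy()
        for _ in range(5):
            repeated = _apply_kraus_qubit(repeated, _damping_kraus(noise), 0, 1)
        once = _apply_kraus_qubit(rho, _damping_kraus(noise.composed(5)), 0, 1)
        assert np.abs(repeated - once).max() < 1e-12


class TestEmulatedFid:
    def test_t0_is_exactly_one(self, methyl):
        est, se = nm.emulated_fid_point(methyl, 0.0, 1, None, nm.NoiseModel(0, 0),
                                        shots=100, seed=0)
        assert est == 1.0

    def test_exact_distribution_matches_exact_dynamics(self, methyl, methyl_h):
        # noiseless, infinite-shot limit with a whole-molecule cluster
        t = 0.31
        est, _ = nm.emulated_fid_point(methyl, t, 2, [(0, 1, 2, 3)],
                                       nm.NoiseModel(0, 0), shots=None, seed=0)
        fid = nm.fid_trace_formula(methyl_h, nm.weighted_total_magnetization(methyl),
                                   np.array([t]))
        assert abs(est - fid.values[0]) < 1e-9

    def test_sampled_estimate_consistent_with_exact(self, methyl):
        # large-shot sampling agrees with the exact distribution within 3 sigma
        t, clusters = 0.17, [(0, 1, 2, 3)]
        exact, _ = nm.emulated_fid_point(methyl, t, 1, clusters, nm.NoiseModel(0, 0),
                                         shots=None, seed=0)
        est, se = nm.emulated_fid_point(methyl, t, 1, clusters, nm.NoiseModel(0, 0),
                                        shots=10**6, seed=42)
        assert abs(est - exact) < 3 * se

    def test_phase_damping_monotonically_quenches_oscillation(self, methyl):
        # q = 1/2 wipes all coherences after one gate, leaving the fully
        # decohered baseline; the distance from that baseline (the surviving
        # oscillating component) must shrink strictly as p_phase grows
        def value(q):
            est, _ = nm.emulated_fid_point(methyl, 0.5, 2, [(0, 1, 2, 3)],
                                           nm.NoiseModel(0.0, q), shots=None, seed=0,
                                           cluster_cost="couplings")
            return est

        baseline = value(0.5)
        osc = [abs(value(q) - baseline) for q in (0.0, 0.05, 0.15, 0.3)]
        assert osc[0] > 1e-4  # the circuit does oscillate at this time
        assert np.all(np.diff(osc) < 0)

    def test_deterministic_given_seed(self, methyl):
        kw = dict(t=0.4, n_steps=2, clusters=[(0, 1, 2, 3)],
                  noise=nm.NoiseModel(0.005, 0.035), shots=500,
                  cluster_cost="couplings")
        a = nm.emulated_fid_point(methyl, seed=123, **kw)
        b = nm.emulated_fid_point(methyl, seed=123, **kw)
        assert a == b


class TestBhattacharyya:
    def test_identical_distributions(self):
        p = np.array([0.2, 0.3, 0.5])
        assert np.isclose(nm.bhattacharyya(p, p), 1.0)

    def test_disjoint_supports(self):
        assert nm.bhattacharyya(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_closed_form_example(self):
        bc = nm.bhattacharyya(np.array([1.0, 0.0]), np.array([0.5, 0.5]))
        assert np.isclose(bc, 1 / np.sqrt(2))
        assert np.isclose(nm.bhattacharyya(np.array([1.0, 0.0]), np.array([0.5, 0.5]),
                                           squared=True), 0.5)

    def test_symmetry_and_discrimination(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(16))
        q = rng.dirichlet(np.ones(16))
        assert np.isclose(nm.bhattacharyya(p, q), nm.bhattacharyya(q, p))
        # resampled copy of p overlaps itself better than an independent q
        counts = rng.multinomial(2000, p) / 2000
        assert nm.bhattacharyya(p, counts) > nm.bhattacharyya(p, q)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            nm.bhattacharyya(np.ones(2) / 2, np.ones(3) / 3)
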