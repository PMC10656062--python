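"""Fixtures, synthetic molecules, file I/O, pipeline plumbing and the CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import nmremu as nm
from nmremu import io as nio
from nmremu.cli import main as cli_main
from nmremu.io import FormatError


class TestAcetonitrileFixture:
    def test_site_count_and_isotopes(self, methyl):
        assert methyl.n_sites == 4
        assert [s.label for s in methyl.sites] == ["13C", "1H", "1H", "1H"]

    def test_exactly_three_couplings(self, methyl):
        assert np.count_nonzero(np.triu(methyl.j_hz, 1)) == 3

    def test_all_couplings_equal_j(self, methyl):
        nz = methyl.j_hz[np.nonzero(methyl.j_hz)]
        assert np.allclose(nz, 136.2)


class TestRandomClusteredSystem:
    def test_block_structure_audit(self):
        system = nm.random_clustered_system(2, (4, 4), seed=0)
        assert system.n_sites == 8
        intra_a = system.j_hz[:4, :4][np.triu_indices(4, 1)]
        intra_b = system.j_hz[4:, 4:][np.triu_indices(4, 1)]
        assert np.all(intra_a != 0) and np.all(intra_b != 0)
        assert np.count_nonzero(system.j_hz[:4, 4:]) == 1

    def test_same_seed_identical(self):
        a = nm.random_clustered_system(2, (4, 4), seed=5)
        b = nm.random_clustered_system(2, (4, 4), seed=5)
        assert np.array_equal(a.j_hz, b.j_hz)

    def test_decoupled_clusters_give_product_structure_fid(self):
        # with zero bridges the raw trace is the 2^(N-Nc)-weighted sum of the
        # per-cluster raw traces (cross terms vanish because Tr[M_c] = 0)
        system = nm.random_clustered_system(2, (4, 4), inter_j=0.0, seed=3)
        h = nm.build_hamiltonian(system)
        obs = nm.weighted_total_magnetization(system)
        times = np.linspace(0, 0.05, 9)
        full = nm.fid_trace_formula(h, obs, times, normalize=False)
        combined = np.zeros(len(times))
        for block in (slice(0, 4), slice(4, 8)):
            sub = nm.SpinSystem(system.sites[block], system.j_hz[block, block])
            sub_fid = nm.fid_trace_formula(nm.build_hamiltonian(sub),
                                           nm.weighted_total_magnetization(sub),
                                           times, normalize=False)
            combined += 2**4 * sub_fid.values
        assert np.abs(full.values - combined).max() < 1e-10 * abs(combined[0])

    def test_weak_coupling_constraint(self):
        with pytest.raises(ValueError, match="weaker"):
            nm.random_clustered_system(2, (4, 4), intra_j=10.0, inter_j=10.0, seed=0)

    def test_size_cap(self):
        with pytest.raises(ValueError, match="cap"):
            nm.random_clustered_system(3, (5, 7), seed=0)


class TestSpinSystemIO:
    def test_roundtrip(self, methyl, tmp_path):
        path = tmp_path / "system.yaml"
        nio.write_spin_system(methyl, path)
        back = nio.read_spin_system(path)
        assert [s.label for s in back.sites] == [s.label for s in methyl.sites]
        assert np.allclose(back.j_hz, methyl.j_hz)

    @pytest.mark.parametrize("mutation,match", [
        ({"sites": ["1H", "XX"], "J_hz": [[0, 1], [1, 0]]}, "unknown isotope"),
        ({"sites": ["1H", "13C"], "J_hz": [[0, 1], [2, 0]]}, "symmetric"),
        ({"sites": ["1H", "13C"], "J_hz": [[1, 0], [0, 0]]}, "diagonal"),
        ({"sites": ["1H", "13C"]}, "missing required key"),
        ({"sites": ["1H"], "J_hz": [[0, 1], [1, 0]]}, "must be 1x1"),
    ])
    def test_malformed_config_reports_offender(self, tmp_path, mutation, match):
        import yaml

        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(mutation))
        with pytest.raises(FormatError, match=match):
            nio.read_spin_system(path)


class TestTabularIO:
    def test_fid_roundtrip(self, tmp_path):
        fid = nm.FIDTrace(np.linspace(0, 1, 8), np.arange(8.0))
        nio.write_fid(fid, tmp_path / "fid.csv")
        back = nio.read_fid(tmp_path / "fid.csv")
        assert np.allclose(back.times, fid.times)
        assert np.allclose(back.values, fid.values)

    def test_schedule_roundtrip(self, tmp_path):
        sched = nm.poisson_gap_schedule(256, 32, seed=1)
        nio.write_schedule(sched, tmp_path / "sched.txt")
        back = nio.read_schedule(tmp_path / "sched.txt", n_grid=256)
        assert np.array_equal(back.indices, sched.indices)

    @pytest.mark.parametrize("content,match", [
        ("wrong,header\n0,1\n", "expected header"),
        ("time_s,value\n0,1,2\n", "two comma-separated"),
        ("time_s,value\n0,abc\n", "non-numeric"),
        ("time_s,value\n", "no data rows"),
        ("time_s,value\n1,1\n0,2\n", "strictly increasing"),
    ])
    def test_malformed_fid_file_line_diagnostics(self, tmp_path, content, match):
        path = tmp_path / "bad.csv"
        path.write_text(content)
        with pytest.raises(FormatError, match=match):
            nio.read_fid(path)

    def test_malformed_schedule_line_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0\n5\nfoo\n")
        with pytest.raises(FormatError, match=r"bad.txt:3"):
            nio.read_schedule(path, n_grid=64)


@pytest.fixture(scope="module")
def small_exact(methyl):
    # exact backend, fully sampled grid (Nyquist above 2J): peaks at J and 2J
    config = nm.PipelineConfig(backend="exact", n_grid=4096, n_keep=4096,
                               t_max=6.0, seed=0)
    return nm.run_pipeline(config, methyl)


class TestPipeline:
    def test_exact_full_sampling_recovers_both_lines(self, small_exact):
        centers = [p.center for p in small_exact.peaks_recon]
        half_grid = 1 / (2 * 6.0)
        assert abs(centers[0] - 136.2) <= half_grid
        assert abs(centers[1] - 272.4) <= half_grid

    def test_record_carries_config_and_stages(self, small_exact):
        rec = small_exact.record.as_dict()
        assert rec["config"]["backend"] == "exact"
        assert {"schedule", "fid", "ist-s"} <= set(rec["stage_seconds"])

    def test_emulated_run_is_bit_identical_across_repeats(self, methyl):
        config = nm.PipelineConfig(seed=21, n_grid=512, n_keep=48, t_max=1.5,
                                   shots=200, step_s=0.25)
        a = nm.run_pipeline(config, methyl)
        b = nm.run_pipeline(config, methyl)
        assert np.array_equal(a.fid.values, b.fid.values)
        assert np.array_equal(a.spectrum_recon.intensities, b.spectrum_recon.intensities)
        assert [p.center for p in a.peaks_recon] == [p.center for p in b.peaks_recon]

    def test_stage_errors_name_the_stage(self, methyl):
        config = nm.PipelineConfig(backend="exact", n_grid=64, n_keep=64,
                                   n_peaks=50, seed=0)
        with pytest.raises(RuntimeError, match="fit-raw"):
            nm.run_pipeline(config, methyl)


class TestCli:
    def test_simulate_exact_prints_lines(self):
        result = CliRunner().invoke(cli_main, ["simulate-exact"])
        assert result.exit_code == 0
        assert "136.2000 Hz" in result.output
        assert "272.4000 Hz" in result.output

    def test_schedule_roundtrip(self, tmp_path):
        out = tmp_path / "sched.txt"
        result = CliRunner().invoke(
            cli_main, ["schedule", "--n-grid", "512", "--n-keep", "32",
                       "--seed", "3", "--out", str(out)])
        assert result.exit_code == 0
        assert len(out.read_text().split()) == 32

    def test_powder_reports_decomposition(self):
        result = CliRunner().invoke(
            cli_main, ["powder", "--system", "dipolar-toy", "--seed", "2",
                       "--n-orientations", "30", "--shots-per", "20"])
        assert result.exit_code == 0
        assert "variance: total" in result.output

    def test_pipeline_writes_artifacts(self, tmp_path):
        out = tmp_path / "run"
        result = CliRunner().invoke(
            cli_main, ["pipeline", "--seed", "1", "--backend", "exact",
                       "--n-keep", "400", "--out-dir", str(out)])
        assert result.exit_code == 0, result.output
        record = json.loads((out / "run_record.json").read_text())
        assert record["seed"] == 1
        for name in ("schedule.txt", "spectrum_reconstructed.csv",
                     "peaks_reconstructed.csv"):
            assert (out / name).exists()
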