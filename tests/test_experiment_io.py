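import json

import numpy as np
import pytest
from click.testing import CliRunner

from nanopost.cli import main as cli_main
from nanopost.experiment_io import (
    ConfigError,
    RunConfig,
    dump_config,
    load_config,
    make_fixture,
    read_trajectory,
    sweep,
    write_manifest,
    write_trajectory,
)
from nanopost.md_engine import IntegratorConfig, Trajectory, integrate, run_experiment
from nanopost.polymer_model import build_initial_conformation, make_topology

TINY_YAML = """
N: 16
blocks: diblock
b: 20.0
S_p: 6.0
d_p: 3.0
n_y: 2
n_z: 2
dt: 0.005
T: 1.0
thermostat: langevin
gamma_or_tau: 1.0
n_equil: 500
n_prod: 1000
sample_interval: 250
seed: 42
replicas: 2
orientation: parallel
"""


class TestConfig:
    def test_roundtrip(self):
        cfg = load_config(TINY_YAML)
        again = load_config(dump_config(cfg))
        assert again == cfg

    def test_unknown_key_named(self):
        with pytest.raises(ConfigError, match="bogus"):
            load_config("N: 10\nbogus: 1\n")

    def test_both_diameters_rejected(self):
        with pytest.raises(ConfigError, match="D_p"):
            load_config("N: 10\nS_p: 6.0\nD_p: 2.0\nd_p: 2.9\n")

    def test_invalid_value_named(self):
        with pytest.raises(ConfigError, match="thermostat"):
            load_config("N: 10\nthermostat: maxwell_demon\n")
        with pytest.raises(ConfigError, match="N"):
            load_config("N: 1\n")

    def test_free_chain_config(self):
        cfg = load_config("N: 10\nblocks: flexible\n")
        assert not cfg.has_array
        assert cfg.derive_array() is None


def small_trajectory(n_frames=5, with_array=True):
    topo = make_topology(8, "diblock")
    arr = None
    if with_array:
        from nanopost.array_geometry import derive_geometry

        arr = derive_geometry(6.0, d_p=3.0)
    rng = np.random.default_rng(0)
    frames = rng.normal(size=(n_frames, 8, 3))
    return Trajectory(
        frames=frames, times=np.arange(1.0, n_frames + 1.0),
        potential=np.zeros(n_frames), kinetic=np.zeros(n_frames),
        topology=topo, array=arr,
    )


class TestXYZ:
    def test_roundtrip_exact(self, tmp_path):
        traj = small_trajectory()
        path = tmp_path / "t.xyz"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        assert np.array_equal(back.frames, traj.frames)  # bitwise
        assert back.times == pytest.approx(traj.times)
        assert back.topology == traj.topology
        assert back.array == traj.array

    def test_empty_roundtrip(self, tmp_path):
        traj = small_trajectory(n_frames=0)
        path = tmp_path / "empty.xyz"
        write_trajectory(traj, path)
        assert read_trajectory(path).n_frames == 0

    def test_frame_count_preserved(self, tmp_path):
        traj = small_trajectory(n_frames=100)
        path = tmp_path / "many.xyz"
        write_trajectory(traj, path)
        assert read_trajectory(path).n_frames == 100

    def test_malformed_reports_line(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("3\ntime=0\nF 0 0 0\nF 1 0\nF 2 0 0\n")
        with pytest.raises(ConfigError, match="line 4"):
            read_trajectory(path)


class TestFixtures:
    def test_rod(self):
        fx = make_fixture("rod", N=11, l=0.97)
        assert fx.expected["span"] == pytest.approx(9.7)

    def test_two_bead(self):
        fx = make_fixture("two_bead", r=2.0)
        assert fx.expected["sq"](np.array([1.0]))[0] == pytest.approx(
            (1 + np.sin(2.0) / 2.0) / 2.0)

    def test_cell_filling(self):
        fx = make_fixture("cell_filling", cells=[(0, 0), (1, 0), (1, 0)])
        assert fx.expected["n"] == 2

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            make_fixture("dodecahedron")


class TestRunExperiment:
    def test_deterministic_and_distinct_replicas(self):
        cfg = load_config(TINY_YAML)
        t1 = run_experiment(cfg)
        t2 = run_experiment(cfg)
        assert len(t1) == 2
        assert np.array_equal(t1[0].frames, t2[0].frames)  # bit-identical rerun
        assert not np.array_equal(t1[0].frames, t1[1].frames)
        seeds = [t.metadata["seed"] for t in t1]
        assert len(set(seeds)) == 2

    def test_manifest(self, tmp_path):
        cfg = load_config(TINY_YAML)
        trajs = run_experiment(cfg)
        man = write_manifest(tmp_path / "m.json", cfg, trajs)
        loaded = json.loads((tmp_path / "m.json").read_text())
        assert loaded["config"]["seed"] == 42
        assert len(loaded["seeds"]) == 2
        assert "R_s" in loaded["observables"]


@pytest.fixture()
def base():
    return RunConfig(N=12, blocks="flexible", S_p=6.0, d_p=3.0,
                     n_equil=500, n_prod=1000, sample_interval=250,
                     seed=7, replicas=1)


class TestSweep:

    def test_constant_sp_columns_and_F(self, base):
        table = sweep("constant_Sp", [1.9, 3.0], base)
        assert list(table["S_p"]) == [6.0, 6.0]
        # F formula at the endpoints
        assert table["F"].iloc[0] == pytest.approx(
            np.pi * 1.9 ** 2 / (4 * 36), rel=1e-12)
        for col in ("w", "d_c", "dc_over_w", "R_s", "n", "Rg", "Rg_par",
                    "Rg_perp"):
            assert col in table.columns

    def test_constant_w_identity(self, base):
        table = sweep("constant_w", [5.0, 6.0], base)
        assert table["d_p"].values == pytest.approx(table["S_p"].values - 3.0)

    def test_infeasible_rows_skipped(self, base):
        messages = []
        table = sweep("constant_Sp", [3.0, 6.0, 9.0], base, log=messages.append)
        assert len(table) == 1
        assert len(messages) == 2
        assert "passage closed" in messages[0] or "skipping" in messages[0]

    def test_row_order_independence(self, base):
        fwd = sweep("constant_Sp", [1.9, 3.0], base)
        rev = sweep("constant_Sp", [3.0, 1.9], base)
        fwd_row = fwd[fwd.d_p == 1.9].iloc[0]
        rev_row = rev[rev.d_p == 1.9].iloc[0]
        assert fwd_row["R_s"] == rev_row["R_s"]

    def test_unknown_protocol(self, base):
        with pytest.raises(ValueError):
            sweep("constant_F", [1.0], base)


class TestCLI:
    def test_theory_geometry(self):
        res = CliRunner().invoke(cli_main,
                                 ["theory", "geometry", "--Sp", "12", "--dp", "11.1"])
        assert res.exit_code == 0, res.output
        header, row = res.output.strip().splitlines()
        vals = dict(zip(header.split(","), row.split(",")))
        assert float(vals["F"]) == pytest.approx(0.672, abs=5e-4)
        assert float(vals["dc_over_w"]) == pytest.approx(6.52, abs=5e-3)

    def test_theory_transition(self):
        res = CliRunner().invoke(cli_main, ["theory", "transition"])
        assert res.exit_code == 0, res.output
        data = json.loads(res.output)
        assert data["flexible"] == pytest.approx(1.5157, abs=1e-3)
        assert data["semiflexible"] == pytest.approx(4.63, abs=5e-3)

    def test_simulate_and_analyze(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(TINY_YAML.replace("replicas: 2", "replicas: 1"))
        runner = CliRunner()
        res = runner.invoke(cli_main, ["simulate", str(cfg_path),
                                       "--outdir", str(tmp_path / "runs")])
        assert res.exit_code == 0, res.output
        traj_path = tmp_path / "runs" / "traj_rep0.xyz"
        assert traj_path.exists()
        res2 = runner.invoke(cli_main, ["analyze", str(traj_path),
                                        "--observables", "span,rg,occupation"])
        assert res2.exit_code == 0, res2.output
        report = json.loads(res2.output)
        assert set(report) >= {"R_s", "Rg", "n"}

    def test_sweep_cli(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(TINY_YAML)
        res = CliRunner().invoke(cli_main, [
            "sweep", "--protocol", "constant_Sp", "--config", str(cfg_path),
            "--grid", "1.9,3.0"])
        assert res.exit_code == 0, res.output
        assert res.output.splitlines()[0].startswith("S_p,")
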