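"""Sliding windows, parameter sweeps, file I/O and the CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from npentropy import (
    compute_entropy,
    npe_value,
    periodic_signal,
    read_signal,
    sliding_profile,
    sweep_1d,
    sweep_2d,
    uniform_random_signal,
    write_results,
)
from npentropy.cli import main as cli_main
from npentropy.workflows import grid_values, write_signal


class TestSlidingProfile:
    def test_window_count_formula(self):
        x = uniform_random_signal(3970, seed=0)
        profile = sliding_profile(x, "pe", 1000, 30, d=3)
        assert profile.n_windows == 100
        assert profile.offsets[0] == 1
        assert profile.offsets[-1] + 1000 - 1 <= 3970

    def test_single_window_equals_whole_signal(self):
        x = uniform_random_signal(1000, seed=1)
        profile = sliding_profile(x, "pe", 1000, 30, d=3)
        assert profile.n_windows == 1
        assert profile.values[0] == pytest.approx(compute_entropy(x, "pe", 3))

    def test_stationary_signal_identical_windows(self):
        x = periodic_signal([1, 2, 3, 4, 5], 4000)
        profile = sliding_profile(x, "npe", 1000, 500, d=3, error=0.0005)
        assert profile.n_windows == 7
        np.testing.assert_allclose(profile.values, profile.values[0], atol=1e-12)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="exceeds signal length"):
            sliding_profile(np.arange(50.0), "pe", 100, 10, d=3)


class TestSweeps:
    def test_1d_grid_point_counts(self):
        assert len(grid_values(3.4, 4.0, step=0.0024)) == 251
        assert len(grid_values(-2.0, 8.0, step=0.04)) == 251
        assert len(grid_values(0.0, 1.0, n_points=11)) == 11

    def test_degenerate_sweep_equals_direct_call(self):
        result = sweep_1d(
            "logistic", "mu", 3.6, 3.6, n_points=1, method="pe", d=4, n=800
        )
        from npentropy import logistic_series, pe

        assert result.values[0] == pytest.approx(pe(logistic_series(3.6, 800), 4))

    def test_logistic_periodic_window_below_chaotic_band(self):
        result = sweep_1d(
            "logistic", "mu", 3.4, 4.0, step=0.02, method="npe", d=5, error=0.005, n=1000
        )
        mu = result.axes["mu"]
        window = np.nanmean(result.values[(mu >= 3.63) & (mu <= 3.74)])
        band = np.nanmean(result.values[mu >= 3.9])
        assert window < band

    def test_single_cell_plane_equals_direct_call(self):
        result = sweep_2d(
            "fractional_henon",
            "a", (1.0, 1.0, None, 1),
            "nu", (0.9, 0.9, None, 1),
            method="pe", d=4, n=400, b=0.2,
        )
        from npentropy import fractional_henon_series, pe

        direct = pe(fractional_henon_series(1.0, 0.2, 0.9, 400), 4)
        assert result.values[0, 0] == pytest.approx(direct)

    def test_failed_cells_flagged_not_fatal(self):
        result = sweep_1d(
            "fractional_henon", "a", 1.0, 6.0, step=2.5,
            method="pe", d=4, n=300, b=0.3, x0=1.0, y0=1.0, nu=0.9,
        )
        assert np.isnan(result.values).any()
        assert np.isfinite(result.values).any()

    def test_unknown_generator_rejected(self):
        with pytest.raises(ValueError, match="unknown generator"):
            sweep_1d("rossler", "c", 0.0, 1.0, step=0.5, method="pe", d=3)


class TestSignalIO:
    def test_ascii_round_trip(self, tmp_path):
        path = tmp_path / "sig.txt"
        x = uniform_random_signal(100, seed=3)
        write_signal(x, path, header="generator=random seed=3")
        back = read_signal(path)
        np.testing.assert_allclose(back, x, atol=1e-11)

    def test_ascii_with_comments(self, tmp_path):
        path = tmp_path / "sig.txt"
        path.write_text("# header\n1\n3\n\n4\n")
        np.testing.assert_array_equal(read_signal(path), [1, 3, 4])

    def test_csv_column_selection(self, tmp_path):
        path = tmp_path / "sig.csv"
        path.write_text("1,10\n2,20\n3,30\n")
        np.testing.assert_array_equal(read_signal(path, column=2), [10, 20, 30])

    def test_non_numeric_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("1\n2\nbogus\n")
        with pytest.raises(ValueError, match="line 3"):
            read_signal(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("# only comments\n")
        with pytest.raises(ValueError, match="no data"):
            read_signal(path)


class TestWriteResults:
    def test_json_round_trip_profile(self, tmp_path):
        x = periodic_signal([1, 2, 3, 4], 300)
        profile = sliding_profile(x, "pe", 100, 50, d=3)
        path = tmp_path / "profile.json"
        write_results(profile, path, format="json")
        assert json.loads(path.read_text()) == profile.to_dict()

    def test_json_round_trip_sweep(self, tmp_path):
        result = sweep_1d("logistic", "mu", 3.5, 3.6, n_points=3, method="pe", d=3, n=300)
        path = tmp_path / "sweep.json"
        write_results(result, path, format="json")
        assert json.loads(path.read_text()) == result.to_dict()

    def test_tsv_carries_config_echo(self, tmp_path):
        x = periodic_signal([1, 2, 3, 4, 5], 500)
        result = npe_value(x, 3, 0.0005)
        path = tmp_path / "npe.tsv"
        write_results(result, path, format="tsv")
        text = path.read_text()
        assert text.startswith("#")
        assert "error=0.0005" in text and "d=3" in text

    def test_sweep_2d_tsv_matrix_layout(self, tmp_path):
        result = sweep_2d(
            "logistic", "mu", (3.5, 3.6, None, 2), "x0", (0.2, 0.4, None, 2),
            method="pe", d=3, n=200,
        )
        path = tmp_path / "grid.tsv"
        write_results(result, path, format="tsv")
        rows = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(rows) == 3  # header + 2 axis rows
        assert len(rows[1].split("\t")) == 3


class TestCli:
    def test_compute_npe_with_network_export(self, tmp_path):
        runner = CliRunner()
        sig = tmp_path / "sig.txt"
        write_signal(periodic_signal([1, 2, 3, 4, 5], 300), sig)
        edges = tmp_path / "edges.tsv"
        graphml = tmp_path / "net.graphml"
        result = runner.invoke(
            cli_main,
            ["compute", str(sig), "--method", "npe", "--d", "3", "--error", "0.0005",
             "--network-out", str(edges), "--graphml-out", str(graphml)],
        )
        assert result.exit_code == 0, result.output
        payload = json.loads(result.output)
        assert 0.0 <= payload["value"] <= 1.0
        assert edges.read_text().startswith("#")
        import networkx as nx

        g = nx.read_graphml(graphml)
        assert g.number_of_nodes() == payload["n_nodes"]

    def test_generate_then_window(self, tmp_path):
        runner = CliRunner()
        sig = tmp_path / "logistic.txt"
        gen = runner.invoke(cli_main, ["generate", "logistic", "--mu", "4.0", "--n", "1500",
                                       "--out", str(sig)])
        assert gen.exit_code == 0, gen.output
        out = tmp_path / "profile.tsv"
        win = runner.invoke(
            cli_main,
            ["window", str(sig), "--method", "pe", "--d", "3", "--window", "500",
             "--step", "250", "--out", str(out)],
        )
        assert win.exit_code == 0, win.output
        rows = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert len(rows) == 1 + 5  # header + floor((1500-500)/250)+1 windows

    def test_sweep_command(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sweep.json"
        result = runner.invoke(
            cli_main,
            ["sweep", "--generator", "logistic", "--method", "pe", "--d", "3",
             "--param", "mu:3.5:3.9:0.2", "--n", "400", "--out", str(out),
             "--format", "json"],
        )
        assert result.exit_code == 0, result.output
        payload = json.loads(out.read_text())
        assert len(payload["values"]) == 3
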