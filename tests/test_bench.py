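"""Benchmark grid, subset experiment, scatter export and the CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import pqsar
from pqsar import (BenchmarkPlan, RegressorConfig, evaluate, run_benchmark,
                   split_panel, subset_experiment, write_stats)
from pqsar.bench import export_scatter, read_scatter, scatter_r2_prd
from pqsar.cli import main as cli_main

from conftest import linear_panel

FAST = {
    "pls": {},
    "gp": {"gp_restarts": 2},
    "svr": {"svr_epsilon": (0.1,), "svr_C": (1.0,), "svr_sigma2": (1.0,)},
    "rf": {"rf_ntree": (30,), "rf_mtry": (4,)},
}


def small_panels(tmp_path, n_panels=2, n=60):
    paths = []
    for i in range(n_panels):
        panel, _ = linear_panel(seed=100 + i, n=n, noise_sd=0.3,
                                panel_id=f"bench{i}")
        path = tmp_path / f"bench{i}.tsv"
        pqsar.write_panel(panel, path)
        paths.append(path)
    return paths


class TestRunBenchmark:
    def test_grid_cardinality(self, tmp_path):
        paths = small_panels(tmp_path, n_panels=2)
        plan = BenchmarkPlan(panels=tuple(paths),
                             aads=("VHSE_ortho", "VHSE"),
                             methods=("pls", "gp"), seeds=(0,),
                             cv_folds=4, cv_mode="none")
        frame, evals = run_benchmark(plan, config_overrides=FAST)
        assert len(frame) == 8
        assert frame["error"].eq("").all()
        assert len(evals) == 8

    def test_row_matches_direct_evaluate(self, tmp_path):
        paths = small_panels(tmp_path, n_panels=1)
        plan = BenchmarkPlan(panels=(paths[0],), aads=("VHSE_ortho",),
                             methods=("pls",), seeds=(3,), cv_folds=4,
                             cv_mode="nested")
        frame, _ = run_benchmark(plan)
        panel = pqsar.prepare_panel(paths[0])
        direct = evaluate(panel, pqsar.get_table("VHSE_ortho"),
                          RegressorConfig(method="pls", cv_folds=4, seed=3),
                          split_panel(panel, 3, 1 - plan.test_fraction))
        row = frame.iloc[0]
        assert row["r2_prd"] == direct.r2_prd
        assert row["r2_cv"] == direct.r2_cv

    def test_corrupt_panel_is_isolated(self, tmp_path):
        paths = small_panels(tmp_path, n_panels=2)
        bad = tmp_path / "corrupt.tsv"
        bad.write_text("sequence\tnot_blu\nACD\t1\n")
        plan = BenchmarkPlan(panels=(paths[0], bad, paths[1]),
                             aads=("VHSE_ortho",), methods=("pls",),
                             cv_folds=4, cv_mode="none")
        frame, _ = run_benchmark(plan)
        assert len(frame) == 3
        ok = frame[frame["error"] == ""]
        assert len(ok) == 2
        assert frame.loc[frame["panel"] == "corrupt", "error"].str.len().gt(0).all()

    def test_empty_plan_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            BenchmarkPlan(panels=(), aads=("VHSE",), methods=("pls",))

    def test_byte_identical_stats_for_same_plan(self, tmp_path):
        paths = small_panels(tmp_path, n_panels=1, n=80)
        plan = BenchmarkPlan(panels=(paths[0],), aads=("VHSE_ortho",),
                             methods=("pls", "gp"), seeds=(1,), cv_folds=4,
                             cv_mode="none")
        outs = []
        for name in ("s1.csv", "s2.csv"):
            frame, _ = run_benchmark(plan, config_overrides=FAST)
            write_stats(frame, tmp_path / name)
            outs.append((tmp_path / name).read_bytes())
        assert outs[0] == outs[1]


class TestSubsetExperiment:
    def test_sizes_and_full_panel_row(self, tmp_path):
        panel, _ = linear_panel(seed=7, n=120, noise_sd=0.3)
        frame = subset_experiment(panel, "VHSE_ortho", ["pls"], [45, 90],
                                  seed=2, cv_mode="none")
        assert list(frame["size"]) == [45, 90, 120]
        assert (frame.groupby("size").size() == 1).all()

    def test_oversize_rejected(self):
        panel, _ = linear_panel(seed=7, n=50, noise_sd=0.3)
        with pytest.raises(ValueError, match="exceed"):
            subset_experiment(panel, "VHSE_ortho", ["pls"], [60], seed=0)

    def test_deterministic(self):
        panel, _ = linear_panel(seed=8, n=90, noise_sd=0.3)
        f1 = subset_experiment(panel, "VHSE_ortho", ["pls"], [40], seed=5,
                               cv_mode="none")
        f2 = subset_experiment(panel, "VHSE_ortho", ["pls"], [40], seed=5,
                               cv_mode="none")
        pd.testing.assert_frame_equal(f1, f2)


@pytest.fixture(scope="module")
def scatter_stats():
    panel, _ = linear_panel(seed=9, n=90, noise_sd=0.3)
    return evaluate(panel, pqsar.get_table("VHSE_ortho"),
                    RegressorConfig(method="pls", seed=9, cv_folds=4),
                    split_panel(panel, 9))


class TestScatterExport:
    def test_bookkeeping_and_self_consistency(self, scatter_stats, tmp_path):
        stats = scatter_stats
        path = tmp_path / "scatter.tsv"
        export_scatter(stats, path)
        frame = read_scatter(path)
        counts = frame["set"].value_counts()
        assert counts["train_fit"] == stats.n_train
        assert counts["cv_oof"] == stats.n_train
        assert counts["test"] == stats.n_test
        assert scatter_r2_prd(frame) == pytest.approx(stats.r2_prd, abs=1e-12)

    def test_roundtrip(self, scatter_stats, tmp_path):
        stats = scatter_stats
        path = tmp_path / "scatter.tsv"
        export_scatter(stats, path)
        frame = read_scatter(path)
        np.testing.assert_array_equal(
            frame.loc[frame["set"] == "test", "predicted"].to_numpy(),
            stats.predictions["test"])


class TestCli:
    def test_encode_command(self, tmp_path):
        panel, _ = linear_panel(seed=10, n=20, noise_sd=0.1)
        path = tmp_path / "p.tsv"
        pqsar.write_panel(panel, path)
        out = tmp_path / "enc.csv"
        result = CliRunner().invoke(cli_main, [
            "encode", "--panel", str(path), "--aad", "VHSE",
            "--out", str(out)])
        assert result.exit_code == 0, result.output
        assert out.exists() and "20 x 48" in result.output

    def test_simulate_and_benchmark_commands(self, tmp_path):
        spec = tmp_path / "spec.yaml"
        spec.write_text(
            "motif: xxxTxV\nn: 60\nseed: 4\ntarget_r2: 0.8\n"
            "panel_id: cli_panel\n")
        panels = tmp_path / "panels"
        result = CliRunner().invoke(cli_main, [
            "simulate", "--spec", str(spec), "--out", str(panels)])
        assert result.exit_code == 0, result.output

        out = tmp_path / "bench"
        result = CliRunner().invoke(cli_main, [
            "benchmark", "--panels", str(panels), "--aads", "VHSE",
            "--methods", "pls", "--seed", "1", "--cv-mode", "none",
            "--cv-folds", "4", "--out", str(out)])
        assert result.exit_code == 0, result.output
        frame = pd.read_csv(out / "stats.csv")
        assert len(frame) == 1 and frame.loc[0, "method"] == "pls"

    def test_subset_command(self, tmp_path):
        panel, _ = linear_panel(seed=11, n=60, noise_sd=0.2)
        path = tmp_path / "p.tsv"
        pqsar.write_panel(panel, path)
        out = tmp_path / "subset.csv"
        result = CliRunner().invoke(cli_main, [
            "subset", "--panel", str(path), "--aad", "VHSE_ortho",
            "--sizes", "30", "--seed", "0", "--cv-mode", "none",
            "--out", str(out)])
        assert result.exit_code == 0, result.output
        assert list(pd.read_csv(out)["size"]) == [30, 60]
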