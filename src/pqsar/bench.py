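"""Benchmark orchestration: panels x descriptor tables x methods grids,
subset-size experiments, and scatter/stat exports.

``run_benchmark`` evaluates every cell of a plan independently; a failing
cell is recorded with its reason and never aborts the grid.  Stats are
exported as a long-format CSV with a fixed float format so that identical
plans and seeds produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from . import aad
from .models import RegressorConfig
from .panels import (PeptidePanel, filter_valid, log_transform, read_panel,
                     split_panel, subset_panel)
from .stats import ModelStats, evaluate, r_squared, rmse

logger = logging.getLogger(__name__)

STATS_COLUMNS = (
    "panel", "domain", "aad", "method", "seed", "n_train", "n_test",
    "r2_fit", "rmse_fit", "r2_cv", "rmse_cv", "r2_prd", "rmse_prd",
    "params", "error",
)


@dataclass(frozen=True)
class BenchmarkPlan:
    """One grid of evaluations: panels x AADs x methods x split seeds."""

    panels: tuple                      # file paths or PeptidePanel objects
    aads: tuple
    methods: tuple
    seeds: tuple = (0,)
    cv_folds: int = 10
    test_fraction: float = 1 / 3
    cv_mode: str = "nested"
    subset_sizes: tuple | None = None
    out_dir: str | None = None

    def __post_init__(self):
        if not (self.panels and self.aads and self.methods and self.seeds):
            raise ValueError(
                "a benchmark plan needs at least one panel, AAD, method and seed"
            )
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


def prepare_panel(source) -> PeptidePanel:
    """Load (if a path), validate and log-transform a panel."""
    panel = source if isinstance(source, PeptidePanel) else read_panel(source)
    panel, report = filter_valid(panel)
    if report:
        logger.info("panel %s exclusions: %s", panel.panel_id, report)
    return log_transform(panel)


def _stats_row(panel, aad_name, method, seed, stats: ModelStats | None,
               error: str = "") -> dict:
    row = {
        "panel": panel.panel_id, "domain": panel.domain_class,
        "aad": aad_name, "method": method, "seed": seed,
        "n_train": stats.n_train if stats else np.nan,
        "n_test": stats.n_test if stats else np.nan,
        "params": repr(stats.params) if stats else "",
        "error": error,
    }
    for f in ("r2_fit", "rmse_fit", "r2_cv", "rmse_cv", "r2_prd", "rmse_prd"):
        row[f] = getattr(stats, f) if stats else np.nan
    return row


def run_benchmark(plan: BenchmarkPlan, config_overrides: dict | None = None):
    """Evaluate every (panel, AAD, method, seed) cell; return a stats frame.

    Returns ``(stats_frame, evaluations)`` where ``evaluations`` maps the
    cell key to its ModelStats (successful cells only, for scatter export).
    """
    rows, evaluations = [], {}
    overrides = config_overrides or {}
    for source in plan.panels:
        try:
            panel = prepare_panel(source)
        except Exception as exc:  # corrupt panel: record, keep going
            logger.error("panel %s failed to load: %s", source, exc)
            rows.extend(
                _stats_row_for_failure(source, a, m, s, exc)
                for a, m, s in product(plan.aads, plan.methods, plan.seeds)
            )
            continue
        for aad_name, method, seed in product(plan.aads, plan.methods, plan.seeds):
            key = (panel.panel_id, aad_name, method, seed)
            try:
                table = aad.get_table(aad_name)
                split = split_panel(panel, seed, 1 - plan.test_fraction)
                config = RegressorConfig(
                    method=method, cv_folds=plan.cv_folds, seed=seed,
                    **overrides.get(method, {}),
                )
                stats = evaluate(panel, table, config, split,
                                 cv_mode=plan.cv_mode)
                rows.append(_stats_row(panel, aad_name, method, seed, stats))
                evaluations[key] = stats
                logger.info("cell %s: params %s", key, stats.params)
            except Exception as exc:
                logger.error("cell %s failed: %s", key, exc)
                rows.append(_stats_row(panel, aad_name, method, seed, None,
                                       error=str(exc)))
    frame = pd.DataFrame(rows, columns=list(STATS_COLUMNS))
    return frame, evaluations


def _stats_row_for_failure(source, aad_name, method, seed, exc) -> dict:
    row = dict.fromkeys(STATS_COLUMNS, np.nan)
    row.update(panel=str(getattr(source, "panel_id", Path(str(source)).stem)),
               domain="", aad=aad_name, method=method, seed=seed,
               params="", error=str(exc))
    return row


def write_stats(frame: pd.DataFrame, path) -> None:
    """Write the stats frame with a fixed float format (byte-reproducible)."""
    frame.to_csv(path, index=False, float_format="%.12g")


def subset_experiment(panel, table, methods, sizes, seed,
                      cv_folds: int = 10, test_fraction: float = 1 / 3,
                      cv_mode: str = "nested",
                      config_overrides: dict | None = None) -> pd.DataFrame:
    """Learning-curve experiment: nested random subsets, then the full panel.

    Subsets are prefixes of one seeded shuffle of the valid records, so
    subset-1000 is contained in subset-3000 and the size effect is not
    confounded by independent re-sampling.
    """
    panel = prepare_panel(panel)
    table = aad.get_table(table) if isinstance(table, str) else table
    n = len(panel)
    sizes = sorted(int(s) for s in sizes)
    if any(s > n for s in sizes):
        raise ValueError(f"subset size(s) {sizes} exceed the panel size {n}")
    if sizes and sizes[-1] == n:
        sizes = sizes[:-1]
    order = np.random.default_rng(seed).permutation(n)
    overrides = config_overrides or {}
    rows = []
    for size in [*sizes, n]:
        sub = subset_panel(panel, order[:size])
        split = split_panel(sub, seed, 1 - test_fraction)
        for method in methods:
            config = RegressorConfig(method=method, cv_folds=cv_folds,
                                     seed=seed, **overrides.get(method, {}))
            stats = evaluate(sub, table, config, split, cv_mode=cv_mode)
            row = _stats_row(sub, table.name, method, seed, stats)
            row["size"] = size
            rows.append(row)
    return pd.DataFrame(rows, columns=["size", *STATS_COLUMNS])


def export_scatter(stats: ModelStats, path) -> None:
    """Export (sequence, set, experimental, predicted) rows for scatter plots.

    Sets are ``train_fit`` (internal fit), ``cv_oof`` (pooled out-of-fold)
    and ``test`` (external blind prediction).
    """
    pr = stats.predictions
    if not pr:
        raise ValueError("this ModelStats carries no stored predictions")
    with open(path, "w") as fh:
        fh.write("sequence\tset\texperimental\tpredicted\n")
        for seq, obs, hat in zip(pr["train_sequences"], pr["y_train"],
                                 pr["train_fit"]):
            fh.write(f"{seq}\ttrain_fit\t{float(obs)!r}\t{float(hat)!r}\n")
        if pr.get("cv_oof") is not None:
            for seq, obs, hat in zip(pr["train_sequences"], pr["y_train"],
                                     pr["cv_oof"]):
                fh.write(f"{seq}\tcv_oof\t{float(obs)!r}\t{float(hat)!r}\n")
        for seq, obs, hat in zip(pr["test_sequences"], pr["y_test"],
                                 pr["test"]):
            fh.write(f"{seq}\ttest\t{float(obs)!r}\t{float(hat)!r}\n")


def read_scatter(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def scatter_r2_prd(frame: pd.DataFrame) -> float:
    """Recompute the external R^2 from an exported scatter frame."""
    test = frame[frame["set"] == "test"]
    return r_squared(test["experimental"].to_numpy(),
                     test["predicted"].to_numpy())
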