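"""Output writers: per-run solutions, selection frequency, missing values.

All reports are comma-separated with headers and deterministic row order
(ascending unit or feature id); probabilities are printed to 6 decimals.
Every number comes straight from the objective / probability machinery —
there is no report-only arithmetic.
"""

from __future__ import annotations

import csv
import os
from pathlib import Path

import pandas as pd

from .model import Problem, RunConfig, Solution
from .objective import ObjectiveBreakdown, evaluate
from .solver import RunResult

__all__ = ["write_solution_outputs", "read_solution", "summed_solution",
           "missing_values_report", "MISSING_VALUES_COLUMNS"]


def write_solution_outputs(run_result: RunResult,
                           directory: str | os.PathLike) -> list[Path]:
    """One ``output_rNNNN.csv`` (unit id, selected 0/1) per repetition,
    plus ``output_best.csv`` copying the lowest-objective run."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written = []
    for k, sol in enumerate(run_result.solutions, start=1):
        path = d / f"output_r{k:04d}.csv"
        _write_solution(sol, path)
        written.append(path)
    best = d / "output_best.csv"
    _write_solution(run_result.best_solution, best)
    written.append(best)
    return written


def _write_solution(solution: Solution, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["planning_unit", "solution"])
        for uid in sorted(solution.selected):
            w.writerow([uid, int(solution.selected[uid])])


def read_solution(path: str | os.PathLike) -> Solution:
    """Invert :func:`write_solution_outputs` for one file."""
    df = pd.read_csv(path)
    return Solution({int(r.planning_unit): bool(r.solution)
                     for r in df.itertuples()})


def summed_solution(run_result: RunResult,
                    directory: str | os.PathLike) -> Path:
    """Selection frequency across repetitions (``output_ssoln.csv``)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    path = d / "output_ssoln.csv"
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["planning_unit", "number"])
        for uid in sorted(run_result.selection_frequency):
            w.writerow([uid, run_result.selection_frequency[uid]])
    return path


MISSING_VALUES_COLUMNS = [
    "feature_id", "name", "target", "held_amount", "shortfall",
    "target_met", "probability_mode", "probability_target",
    "capture_probability", "expected_amount", "amount_variance",
    "z_score", "probability_shortfall", "probability_target_met",
]


def missing_values_report(problem: Problem, solution: Solution,
                          config: RunConfig,
                          directory: str | os.PathLike,
                          breakdown: ObjectiveBreakdown | None = None
                          ) -> Path:
    """Per-feature target/probability diagnostics (``output_mv.csv``).

    Extends the classic missing-values table with the chance-constraint
    columns: mode, probability target P_j, capture probability p_j,
    expected amount mu_j, variance, z-score, probability shortfall and a
    met flag (true whenever P_j = 0).
    """
    if breakdown is None:
        breakdown = evaluate(problem, solution, config)
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    path = d / "output_mv.csv"
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(MISSING_VALUES_COLUMNS)
        for fs in breakdown.per_feature:
            feat = problem.feature(fs.feature_id)
            ps = fs.probability
            w.writerow([
                fs.feature_id, feat.name, f"{feat.target:g}",
                f"{fs.held_amount:g}", f"{fs.shortfall:g}",
                int(fs.target_met), problem.mode.value,
                f"{feat.probability_target:.6f}",
                f"{ps.capture_probability:.6f}",
                f"{ps.expected_amount:.6f}",
                f"{ps.amount_variance:.6f}",
                "" if ps.z is None else f"{ps.z:.6f}",
                f"{fs.probability_shortfall:.6f}",
                int(fs.probability_target_met),
            ])
    return path
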