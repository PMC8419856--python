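"""Solvers: simulated annealing, steepest-descent improvement, exhaustion.

Annealing proposes uniform single-unit flips among the free (unlocked)
units; a move with objective delta d is accepted when d < 0 or with
probability exp(-d / temperature). The temperature decays geometrically
over a fixed number of steps; by default the initial temperature adapts to
the problem (90th percentile of |delta| over sampled flips) and the final
temperature is 1e-4 of it. The best state ever visited is returned, then
optionally polished by repeated steepest-descent passes. For instances with
at most ~20 free units an exhaustive search provides the certified optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import (
    CapabilityError,
    ConfigurationError,
    Problem,
    RunConfig,
    Solution,
    UnitStatus,
)
from .objective import Evaluator, ObjectiveBreakdown

__all__ = ["AnnealSchedule", "RunResult", "initial_solution", "anneal",
           "improve", "solve_exact", "run_batch"]

_ACCEPT_EPS = 1e-12


@dataclass(frozen=True)
class AnnealSchedule:
    """Cooling schedule: total flips, temperature steps, temperatures.

    ``initial_temperature`` None means adapt to the instance; the final
    temperature defaults to initial / 1e4, which fixes the geometric decay
    factor given the number of steps.
    """

    iterations: int = 100_000
    temperature_steps: int = 100
    initial_temperature: Optional[float] = None
    final_temperature: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.iterations >= self.temperature_steps >= 1:
            raise ConfigurationError(
                "schedule requires iterations >= temperature_steps >= 1 "
                f"(got {self.iterations}, {self.temperature_steps})")


@dataclass
class RunResult:
    """Outcome of a repeated-annealing batch."""

    solutions: list[Solution]
    breakdowns: list[ObjectiveBreakdown]
    best_index: int
    selection_frequency: dict[int, int]

    @property
    def best_solution(self) -> Solution:
        return self.solutions[self.best_index]

    @property
    def best_breakdown(self) -> ObjectiveBreakdown:
        return self.breakdowns[self.best_index]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def initial_solution(problem: Problem, inclusion_fraction: float,
                     rng) -> Solution:
    """Random starting reserve: each free unit joins with the given
    probability; locked-in and initially-selected units always join,
    locked-out units never do."""
    rng = _as_rng(rng)
    sel = {}
    for u in problem.planning_units:
        if u.status is UnitStatus.LOCKED_IN or u.status is UnitStatus.STARTING:
            sel[u.id] = True
        elif u.status is UnitStatus.LOCKED_OUT:
            sel[u.id] = False
        else:
            sel[u.id] = bool(rng.random() < inclusion_fraction)
    return Solution(sel)


def _free_indices(ev: Evaluator) -> list[int]:
    return [i for i, locked in enumerate(ev.locked) if not locked]


def _auto_initial_temperature(ev: Evaluator, free: list[int],
                              rng: np.random.Generator,
                              samples: int = 100) -> float:
    """90th percentile of |delta| over sampled flips from the start state."""
    deltas = []
    for i in rng.integers(0, len(free), size=samples):
        u = free[int(i)]
        d = ev.flip(u)
        ev.flip(u)  # revert
        deltas.append(abs(d))
    t0 = float(np.percentile(deltas, 90)) if deltas else 0.0
    return t0 if t0 > 0 else 1.0


def anneal(problem: Problem, config: RunConfig,
           rng=None) -> tuple[Solution, ObjectiveBreakdown]:
    """One simulated-annealing run; returns the best state visited."""
    rng = _as_rng(rng if rng is not None else config.seed)
    schedule = config.schedule or AnnealSchedule()
    if not isinstance(schedule, AnnealSchedule):
        raise ConfigurationError("config.schedule must be an AnnealSchedule")

    ev = Evaluator(problem, config)
    start = initial_solution(problem, config.initial_inclusion_fraction, rng)
    ev.reset(start)
    free = _free_indices(ev)
    if not free:
        return ev.solution(), ev.breakdown()

    t0 = schedule.initial_temperature
    if t0 is None:
        t0 = _auto_initial_temperature(ev, free, rng)
    t_final = schedule.final_temperature
    if t_final is None:
        t_final = t0 / 1e4
    steps = schedule.temperature_steps
    decay = (t_final / t0) ** (1.0 / steps) if t0 > 0 else 1.0

    best_total = ev.total
    best_sel = list(ev.sel)
    temperature = t0
    per_step = schedule.iterations // steps
    remainder = schedule.iterations - per_step * steps
    flip = ev.flip
    exp = math.exp

    for step in range(steps):
        block = per_step + (1 if step < remainder else 0)
        if block == 0:
            temperature *= decay
            continue
        choices = rng.integers(0, len(free), size=block)
        uniforms = rng.random(block)
        cold = temperature <= 0.0
        for i, u in zip(choices, uniforms):
            unit = free[i]
            d = flip(unit)
            if d < -_ACCEPT_EPS:
                accepted = True
            elif cold or d > 700.0 * temperature:
                accepted = False
            else:
                accepted = u < exp(-d / temperature) if d > 0 else True
            if accepted:
                if ev.total < best_total - _ACCEPT_EPS:
                    best_total = ev.total
                    best_sel = list(ev.sel)
            else:
                flip(unit)  # revert
        temperature *= decay

    ev.sel = best_sel
    best = Solution({i: s for i, s in zip(ev.unit_ids, best_sel)})
    ev.reset(best)
    return best, ev.breakdown()


def improve(problem: Problem, solution: Solution,
            config: RunConfig) -> Solution:
    """Steepest-descent passes of single flips until locally optimal."""
    ev = Evaluator(problem, config)
    ev.reset(solution)
    free = _free_indices(ev)
    while True:
        best_delta = -_ACCEPT_EPS
        best_unit = None
        for u in free:
            d = ev.flip(u)
            ev.flip(u)
            if d < best_delta:
                best_delta = d
                best_unit = u
        if best_unit is None:
            return ev.solution()
        ev.flip(best_unit)


def solve_exact(problem: Problem, config: RunConfig,
                max_free: int = 20) -> tuple[Solution, ObjectiveBreakdown]:
    """Certified optimum by enumerating all selections of free units.

    Ties are broken toward fewer selected units, then lexicographically
    ascending selected-id tuples. Raises :class:`CapabilityError` above
    ``max_free`` free units.
    """
    ev = Evaluator(problem, config)
    free_units = sorted(u.id for u in problem.planning_units
                        if not u.status.locked)
    k = len(free_units)
    if k > max_free:
        raise CapabilityError(
            f"{k} free units exceed the exhaustive-search limit {max_free}")
    locked_in = [u.id for u in problem.planning_units
                 if u.status is UnitStatus.LOCKED_IN]

    best_key = None
    best_sol = None
    for mask in range(1 << k):
        chosen = [free_units[i] for i in range(k) if mask >> i & 1]
        sol = Solution.from_ids(problem, locked_in + chosen)
        ev.reset(sol)
        total = ev.total
        key = (round(total, 9), len(chosen) + len(locked_in),
               tuple(sorted(locked_in + chosen)))
        if best_key is None or key < best_key:
            best_key = key
            best_sol = sol
    ev.reset(best_sol)
    return best_sol, ev.breakdown()


def run_batch(problem: Problem, config: RunConfig) -> RunResult:
    """Repeated anneal + improve with per-repetition derived seeds."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.repetitions)
    solutions = []
    breakdowns = []
    ev = Evaluator(problem, config)
    for child in seeds:
        rng = np.random.default_rng(child)
        sol, _ = anneal(problem, config, rng)
        sol = improve(problem, sol, config)
        ev.reset(sol)
        solutions.append(sol)
        breakdowns.append(ev.breakdown())
        ev = Evaluator(problem, config)  # detach cached evaluator
    best_index = min(range(len(breakdowns)),
                     key=lambda i: (breakdowns[i].total, i))
    freq = {u.id: 0 for u in problem.planning_units}
    for sol in solutions:
        for uid in sol.selected_ids:
            freq[uid] += 1
    return RunResult(solutions=solutions, breakdowns=breakdowns,
                     best_index=best_index, selection_frequency=freq)
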