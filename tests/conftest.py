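import itertools

import numpy as np
import pytest

from marprob import (
    FeatureRecord,
    Occurrence,
    PlanningUnit,
    Problem,
    ProblemMode,
    RunConfig,
    Solution,
    toy_problem,
)


@pytest.fixture
def toy1():
    return toy_problem(1)


@pytest.fixture
def toy2():
    return toy_problem(2)


@pytest.fixture
def toy3():
    return toy_problem(3)


@pytest.fixture
def raw_exact_config():
    """Unit weights, raw shortfall, exact engine — the worked-example setup."""
    return RunConfig(shortfall_style="raw", probability_engine="exact")


def brute_force_tail(carriers, target):
    """Independent oracle: enumerate every present/absent outcome.

    ``carriers`` is a list of (amount, survival probability); returns
    Pr(sum of present amounts >= target), ties counting as success.
    """
    total = 0.0
    for outcome in itertools.product((0, 1), repeat=len(carriers)):
        pr = 1.0
        amt = 0.0
        for present, (r, s) in zip(outcome, carriers):
            pr *= s if present else 1.0 - s
            if present:
                amt += r
        if amt >= target - 1e-12:
            total += pr
    return total


def single_feature_problem(carriers, target, p_target=0.9):
    """A species-mode problem with one feature spread over len(carriers)
    unit-cost units; carrier i sits in unit i+1."""
    units = [PlanningUnit(id=i + 1) for i in range(len(carriers))]
    occs = [Occurrence(feature_id=1, unit_id=i + 1, amount=r,
                       presence_probability=s)
            for i, (r, s) in enumerate(carriers)]
    feat = FeatureRecord(id=1, target=target, probability_target=p_target)
    return Problem(planning_units=units, features=[feat], occurrences=occs,
                   mode=ProblemMode.SPECIES_2D)


def random_carriers(rng, k, grid=True):
    """k random (amount, survival) pairs; non-grid amounts when asked."""
    if grid:
        amounts = rng.integers(1, 4, size=k).astype(float)
    else:
        amounts = np.round(rng.uniform(0.1, 3.0, size=k), 6)
    survival = np.round(rng.uniform(0.0, 1.0, size=k), 6)
    return list(zip(amounts.tolist(), survival.tolist()))


def all_selected(problem):
    return Solution.from_ids(problem, [u.id for u in problem.planning_units])
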