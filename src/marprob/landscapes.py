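"""Worked-example and random landscape generators.

``toy_problem`` builds the three tiny four-unit illustrations of how a
chance constraint changes reserve selection (one or two species occupying
units p2–p4 with the printed occurrence probabilities). ``random_problem``
builds seeded rectangular-grid landscapes with rook adjacency, lognormal
unit costs and beta-distributed probabilities, so every solver and I/O path
is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    BoundarySegment,
    ConfigurationError,
    FeatureRecord,
    Occurrence,
    PlanningUnit,
    Problem,
    ProblemMode,
)

__all__ = ["LandscapeSpec", "toy_problem", "figure1_problem",
           "random_problem"]

#: the three worked examples: per species, {unit id: presence probability}
#: and the probability target; targets are all 1 occurrence
_TOY_EXAMPLES = {
    1: [("species 1", {2: 1.0}, 1.0)],
    2: [("species 2", {2: 0.5, 3: 0.5}, 0.8)],
    3: [("species 3", {2: 0.9, 3: 0.3}, 0.8),
        ("species 4", {2: 0.6, 3: 0.8, 4: 0.1}, 0.9)],
}


def toy_problem(example_id: int) -> Problem:
    """One of the three 4-unit worked examples (ids 1-3).

    Each is a species-mode problem over units p1..p4 with unit costs 1, no
    boundary segments, every occurrence amount 1 and target 1 occurrence;
    only the occurrence probabilities and probability targets differ.
    """
    if example_id not in _TOY_EXAMPLES:
        raise KeyError(f"unknown worked example id {example_id}; "
                       "choose 1, 2 or 3")
    units = [PlanningUnit(id=i, cost=1.0) for i in range(1, 5)]
    feats = []
    occs = []
    for k, (name, presences, p_target) in enumerate(_TOY_EXAMPLES[example_id]):
        fid = k + 1
        feats.append(FeatureRecord(id=fid, target=1.0, penalty_factor=1.0,
                                   probability_target=p_target, name=name))
        for uid, p in sorted(presences.items()):
            occs.append(Occurrence(feature_id=fid, unit_id=uid, amount=1.0,
                                   presence_probability=p))
    occs.sort(key=lambda o: (o.unit_id, o.feature_id))
    return Problem(planning_units=units, features=feats, occurrences=occs,
                   mode=ProblemMode.SPECIES_2D)


#: alias: the examples come from a single illustrated figure
figure1_problem = toy_problem


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of a seeded random grid landscape.

    Costs are lognormal (``cost_log_mean``, ``cost_log_sd`` on the log
    scale); each feature occupies a random ``occupancy_fraction`` of the
    units with amount 1; probabilities (occurrence-level in species mode,
    unit-level loss in threat mode) are Beta(``prob_alpha``, ``prob_beta``).
    """

    grid_rows: int = 5
    grid_cols: int = 5
    n_features: int = 3
    cost_log_mean: float = 0.0
    cost_log_sd: float = 0.5
    prob_alpha: float = 4.0
    prob_beta: float = 2.0
    occupancy_fraction: float = 0.3
    target_fraction: float = 0.5
    probability_target: float = 0.8
    penalty_factor: float = 1.0
    mode: ProblemMode = ProblemMode.SPECIES_2D
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigurationError("grid must have at least one unit")
        if self.n_features < 1:
            raise ConfigurationError("need at least one feature")
        if not 0 < self.occupancy_fraction <= 1:
            raise ConfigurationError("occupancy_fraction must be in (0, 1]")
        for attr in ("cost_log_sd", "prob_alpha", "prob_beta"):
            if getattr(self, attr) <= 0:
                raise ConfigurationError(f"{attr} must be > 0")


def random_problem(spec: LandscapeSpec) -> Problem:
    """Seeded random grid landscape honouring the spec's distributions.

    Units are numbered row-major from 1. Rook-adjacent pairs share a
    boundary of length 1; units on the grid edge additionally carry a
    self-segment whose length is their number of exposed outer edges.
    Feature targets are ``target_fraction`` of each feature's total amount
    (rounded up), so they are always reachable.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid_rows, spec.grid_cols
    n = rows * cols

    def uid(r: int, c: int) -> int:
        return r * cols + c + 1

    costs = rng.lognormal(spec.cost_log_mean, spec.cost_log_sd, size=n)
    threat = spec.mode is ProblemMode.THREAT_1D
    loss = (rng.beta(spec.prob_alpha, spec.prob_beta, size=n)
            if threat else np.zeros(n))
    units = [PlanningUnit(id=i + 1, cost=float(costs[i]),
                          loss_probability=float(loss[i])) for i in range(n)]

    boundaries = []
    for r in range(rows):
        for c in range(cols):
            i = uid(r, c)
            if c + 1 < cols:
                boundaries.append(BoundarySegment(i, uid(r, c + 1), 1.0))
            if r + 1 < rows:
                boundaries.append(BoundarySegment(i, uid(r + 1, c), 1.0))
            exposed = ((r == 0) + (r == rows - 1) + (c == 0)
                       + (c == cols - 1))
            if exposed:
                boundaries.append(BoundarySegment(i, i, float(exposed)))

    n_occupied = max(1, round(spec.occupancy_fraction * n))
    feats = []
    occs = []
    for f in range(1, spec.n_features + 1):
        chosen = rng.choice(n, size=n_occupied, replace=False)
        chosen = np.sort(chosen)
        target = float(np.ceil(spec.target_fraction * n_occupied))
        feats.append(FeatureRecord(
            id=f, target=target, penalty_factor=spec.penalty_factor,
            probability_target=(0.0 if spec.mode is ProblemMode.DETERMINISTIC
                                else spec.probability_target),
            name=f"feature_{f}"))
        if threat or spec.mode is ProblemMode.DETERMINISTIC:
            presence = np.ones(n_occupied)
        else:
            presence = rng.beta(spec.prob_alpha, spec.prob_beta,
                                size=n_occupied)
        for i, p in zip(chosen, presence):
            occs.append(Occurrence(feature_id=f, unit_id=int(i) + 1,
                                   amount=1.0,
                                   presence_probability=float(p)))
    occs.sort(key=lambda o: (o.unit_id, o.feature_id))
    return Problem(planning_units=units, features=feats, occurrences=occs,
                   boundaries=boundaries, mode=spec.mode)
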