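"""Domain model for probabilistic minimum-set reserve selection.

A planning problem consists of planning units (spatial parcels with a cost
and a lock status), conservation features (each with a representation target
``T_j``, a penalty factor ``F_j`` and an optional probability target ``P_j``),
a sparse feature-by-unit occurrence table and a boundary graph. Uncertainty
enters in one of two ways:

* **threat mode (1D)** — each planning unit carries a loss probability
  ``q_i``: the chance that every feature in the unit is lost over the
  planning horizon (catastrophe, degradation, succession).
* **species mode (2D)** — each occurrence carries its own existence
  probability ``1 - q_ij`` (typically a species-distribution-model output
  or a habitat-map accuracy).

The deterministic mode (all probabilities trivial) recovers the classic
minimum-set problem.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "MarProbError",
    "FormatError",
    "ModeConflictError",
    "CapabilityError",
    "ConfigurationError",
    "ContractError",
    "DataValidationError",
    "UnitStatus",
    "ProblemMode",
    "PlanningUnit",
    "FeatureRecord",
    "Occurrence",
    "BoundarySegment",
    "Problem",
    "RunConfig",
    "Solution",
    "Violation",
    "validate",
]


class MarProbError(Exception):
    """Base class for all package errors."""


class FormatError(MarProbError):
    """An input file is malformed (missing column, bad value)."""


class ModeConflictError(FormatError):
    """Both unit-level and occurrence-level probabilities are populated."""


class CapabilityError(MarProbError):
    """The requested computation exceeds what the engine can do exactly."""


class ConfigurationError(MarProbError):
    """A run configuration value is infeasible."""


class ContractError(MarProbError):
    """An operation was called in a state that violates its contract."""


class DataValidationError(MarProbError):
    """A problem failed validation; carries the violation list."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        super().__init__(
            "; ".join(str(v) for v in violations) or "validation failed"
        )


class UnitStatus(enum.IntEnum):
    """Lock status of a planning unit (classic dat-file codes).

    AVAILABLE units are free; STARTING units are free but begin selected;
    LOCKED_IN / LOCKED_OUT units are never flipped by any solver.
    """

    AVAILABLE = 0
    STARTING = 1
    LOCKED_IN = 2
    LOCKED_OUT = 3

    @property
    def locked(self) -> bool:
        return self in (UnitStatus.LOCKED_IN, UnitStatus.LOCKED_OUT)


class ProblemMode(str, enum.Enum):
    DETERMINISTIC = "deterministic"
    THREAT_1D = "threat_1d"
    SPECIES_2D = "species_2d"


@dataclass(frozen=True)
class PlanningUnit:
    """A candidate parcel: id, protection cost, lock status, loss risk.

    ``loss_probability`` (q_i) only has effect in threat (1D) mode: it is the
    chance that all features at the site are lost over the planning horizon.
    """

    id: int
    cost: float = 1.0
    status: UnitStatus = UnitStatus.AVAILABLE
    loss_probability: float = 0.0


@dataclass
class FeatureRecord:
    """A conservation feature and its targets.

    ``target`` (T_j) is the minimum amount required in the selected set;
    ``penalty_factor`` (F_j, SPF) weights the cost of missing it;
    ``probability_target`` (P_j) is the minimum acceptable probability that
    the target is actually achieved given uncertainty — 0 disables the
    chance constraint for this feature. ``representation_cost`` (R_j) is the
    cheapest-set cost of meeting the target, computed and cached lazily.
    """

    id: int
    target: float = 0.0
    penalty_factor: float = 1.0
    probability_target: float = 0.0
    name: str = ""
    representation_cost: Optional[float] = None


@dataclass(frozen=True)
class Occurrence:
    """Amount r_ij of one feature in one unit, with existence probability.

    ``presence_probability`` equals ``1 - q_ij`` in species (2D) mode and is
    1 elsewhere.
    """

    feature_id: int
    unit_id: int
    amount: float
    presence_probability: float = 1.0


@dataclass(frozen=True)
class BoundarySegment:
    """Shared boundary length v_ih between two units.

    A segment with ``unit_id_a == unit_id_b`` is an exposed (outer) edge:
    it contributes to the boundary penalty whenever the unit is selected.
    """

    unit_id_a: int
    unit_id_b: int
    length: float


@dataclass
class Problem:
    """A full reserve-selection instance."""

    planning_units: list[PlanningUnit]
    features: list[FeatureRecord]
    occurrences: list[Occurrence]
    boundaries: list[BoundarySegment] = field(default_factory=list)
    mode: ProblemMode = ProblemMode.DETERMINISTIC

    def __post_init__(self) -> None:
        self._unit_by_id = {u.id: u for u in self.planning_units}
        self._feature_by_id = {f.id: f for f in self.features}

    @property
    def n_units(self) -> int:
        return len(self.planning_units)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def unit(self, unit_id: int) -> PlanningUnit:
        try:
            return self._unit_by_id[unit_id]
        except KeyError:
            raise KeyError(f"unknown planning unit id {unit_id}") from None

    def feature(self, feature_id: int) -> FeatureRecord:
        try:
            return self._feature_by_id[feature_id]
        except KeyError:
            raise KeyError(f"unknown feature id {feature_id}") from None

    def has_unit(self, unit_id: int) -> bool:
        return unit_id in self._unit_by_id

    def has_feature(self, feature_id: int) -> bool:
        return feature_id in self._feature_by_id

    def loss_probability(self, occ: Occurrence) -> float:
        """q_ij: chance the occurrence is absent/lost, by mode."""
        if self.mode is ProblemMode.THREAT_1D:
            return self.unit(occ.unit_id).loss_probability
        if self.mode is ProblemMode.SPECIES_2D:
            return 1.0 - occ.presence_probability
        return 0.0

    def occurrences_of(self, feature_id: int) -> list[Occurrence]:
        if not self.has_feature(feature_id):
            raise KeyError(f"unknown feature id {feature_id}")
        return [o for o in self.occurrences if o.feature_id == feature_id]


@dataclass
class Solution:
    """Selection indicator x_i per planning unit id."""

    selected: dict[int, bool]

    @classmethod
    def from_ids(cls, problem: Problem, ids: Iterable[int]) -> "Solution":
        chosen = set(ids)
        for i in chosen:
            problem.unit(i)  # raises on unknown id
        return cls({u.id: (u.id in chosen) for u in problem.planning_units})

    @classmethod
    def empty(cls, problem: Problem) -> "Solution":
        return cls({u.id: False for u in problem.planning_units})

    @property
    def selected_ids(self) -> list[int]:
        return sorted(i for i, s in self.selected.items() if s)

    def is_selected(self, unit_id: int) -> bool:
        return self.selected.get(unit_id, False)

    def copy(self) -> "Solution":
        return Solution(dict(self.selected))


@dataclass
class RunConfig:
    """Weights, styles and run control for a solve.

    ``boundary_multiplier`` (b, BLM) trades compactness against cost;
    ``representation_weight`` (y) scales the missed-target penalty;
    ``probability_weight`` (w) scales the missed-probability-target penalty.
    ``shortfall_style`` controls the probability shortfall: ``normalized``
    divides (P_j - p_j) by P_j, ``raw`` uses the plain difference.
    ``representation_penalty_style``: ``step`` charges the full F_j R_j when
    the target is missed, ``proportional`` scales it by the relative
    shortfall. ``schedule`` is an :class:`~marprob.solver.AnnealSchedule`
    (None means the solver default). ``initial_inclusion_fraction`` (PROP)
    seeds each run's starting reserve.
    """

    boundary_multiplier: float = 0.0
    representation_weight: float = 1.0
    probability_weight: float = 1.0
    shortfall_style: str = "normalized"
    representation_penalty_style: str = "step"
    repetitions: int = 10
    schedule: Optional[object] = None
    initial_inclusion_fraction: float = 0.5
    seed: int = 0
    probability_engine: str = "normal_approx"
    miss_level: float = 1.0
    input_dir: str = "."
    output_dir: str = "output"
    pu_name: str = "pu.dat"
    spec_name: str = "spec.dat"
    puvspr_name: str = "puvspr.dat"
    bound_name: str = "bound.dat"

    def __post_init__(self) -> None:
        for attr in ("boundary_multiplier", "representation_weight",
                     "probability_weight"):
            if getattr(self, attr) < 0:
                raise ConfigurationError(f"{attr} must be >= 0")
        if self.shortfall_style not in ("normalized", "raw"):
            raise ConfigurationError(
                f"unknown shortfall_style {self.shortfall_style!r}")
        if self.representation_penalty_style not in ("step", "proportional"):
            raise ConfigurationError(
                "unknown representation_penalty_style "
                f"{self.representation_penalty_style!r}")
        if self.probability_engine not in ("normal_approx", "exact"):
            raise ConfigurationError(
                f"unknown probability_engine {self.probability_engine!r}")
        if not 0.0 <= self.initial_inclusion_fraction <= 1.0:
            raise ConfigurationError(
                "initial_inclusion_fraction must lie in [0, 1]")
        if self.repetitions < 1:
            raise ConfigurationError("repetitions must be >= 1")

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Violation:
    """One validation failure: which entity, which field, which rule."""

    entity: str
    field: str
    rule: str

    def __str__(self) -> str:
        return f"{self.entity}: {self.field}: {self.rule}"


def _prob_ok(p: float) -> bool:
    return 0.0 <= p <= 1.0


def validate(problem: Problem) -> list[Violation]:
    """Check every model invariant; return violations (never raises).

    An empty list means the problem is internally consistent: unique ids,
    values in range, referential integrity, and mode-specific probability
    constraints (threat mode forbids per-occurrence probabilities, species
    mode forbids unit-level loss probabilities).
    """
    out: list[Violation] = []

    seen_units: set[int] = set()
    for u in problem.planning_units:
        ent = f"planning_unit {u.id}"
        if u.id in seen_units:
            out.append(Violation(ent, "id", "duplicate id"))
        seen_units.add(u.id)
        if u.id <= 0:
            out.append(Violation(ent, "id", "must be a positive integer"))
        if u.cost < 0:
            out.append(Violation(ent, "cost", "must be >= 0"))
        if not _prob_ok(u.loss_probability):
            out.append(Violation(ent, "loss_probability",
                                 "must lie in [0, 1]"))
        if problem.mode is ProblemMode.SPECIES_2D and u.loss_probability != 0:
            out.append(Violation(
                ent, "loss_probability",
                "species (2D) mode forbids unit-level loss probabilities"))

    seen_feats: set[int] = set()
    for f in problem.features:
        ent = f"feature {f.id}"
        if f.id in seen_feats:
            out.append(Violation(ent, "id", "duplicate id"))
        seen_feats.add(f.id)
        if f.id <= 0:
            out.append(Violation(ent, "id", "must be a positive integer"))
        if f.target < 0:
            out.append(Violation(ent, "target", "must be >= 0"))
        if f.penalty_factor < 0:
            out.append(Violation(ent, "penalty_factor", "must be >= 0"))
        if not _prob_ok(f.probability_target):
            out.append(Violation(ent, "probability_target",
                                 "must lie in [0, 1]"))

    seen_pairs: set[tuple[int, int]] = set()
    for o in problem.occurrences:
        ent = f"occurrence (feature {o.feature_id}, unit {o.unit_id})"
        pair = (o.feature_id, o.unit_id)
        if pair in seen_pairs:
            out.append(Violation(ent, "(feature_id, unit_id)",
                                 "duplicate pair"))
        seen_pairs.add(pair)
        if o.unit_id not in seen_units:
            out.append(Violation(ent, "unit_id",
                                 f"references unknown unit {o.unit_id}"))
        if o.feature_id not in seen_feats:
            out.append(Violation(
                ent, "feature_id",
                f"references unknown feature {o.feature_id}"))
        if not o.amount > 0:
            out.append(Violation(ent, "amount", "must be > 0"))
        if not _prob_ok(o.presence_probability):
            out.append(Violation(ent, "presence_probability",
                                 "must lie in [0, 1]"))
        if (problem.mode is not ProblemMode.SPECIES_2D
                and o.presence_probability != 1.0):
            out.append(Violation(
                ent, "presence_probability",
                f"{problem.mode.value} mode forbids per-occurrence "
                "probabilities"))

    seen_edges: set[tuple[int, int]] = set()
    for b in problem.boundaries:
        ent = f"boundary ({b.unit_id_a}, {b.unit_id_b})"
        edge = (min(b.unit_id_a, b.unit_id_b), max(b.unit_id_a, b.unit_id_b))
        if edge in seen_edges:
            out.append(Violation(ent, "(unit_id_a, unit_id_b)",
                                 "unordered pair stored more than once"))
        seen_edges.add(edge)
        if b.length < 0:
            out.append(Violation(ent, "length", "must be >= 0"))
        for uid in (b.unit_id_a, b.unit_id_b):
            if uid not in seen_units:
                out.append(Violation(ent, "unit_id",
                                     f"references unknown unit {uid}"))

    return out
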