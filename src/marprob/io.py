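"""Reading and writing the Marxan-style dat-file dialect.

Four comma-separated tables with lower-case headers:

* ``pu.dat`` — ``id,cost,status[,prob]`` (``prob`` = unit loss probability,
  threat mode)
* ``spec.dat`` — ``id,target,spf[,ptarget1d][,ptarget2d][,name]``
* ``puvspr.dat`` — ``species,pu,amount[,prob]`` (``prob`` = occurrence
  existence probability, species mode)
* ``bound.dat`` — ``id1,id2,boundary`` (``id1 == id2`` marks an exposed
  outer edge)

plus an ``input.dat`` of ``KEY value`` pairs for run parameters. The mode is
inferred from which probability columns carry non-default values; populating
both is an error. Row order in the files is not significant — the reader
sorts occurrences by unit then feature. Floats are printed with ``repr``
(shortest round-trip form) so write → read is exact.
"""

from __future__ import annotations

import csv
import os
from pathlib import Path

from .model import (
    BoundarySegment,
    ConfigurationError,
    DataValidationError,
    FeatureRecord,
    FormatError,
    ModeConflictError,
    Occurrence,
    PlanningUnit,
    Problem,
    ProblemMode,
    RunConfig,
    UnitStatus,
    validate,
)

__all__ = ["read_problem", "write_problem", "read_input_dat",
           "write_input_dat", "load_run"]


def _read_table(path: Path, required: tuple[str, ...]) -> list[dict]:
    if not path.exists():
        raise FormatError(f"{path.name}: file not found at {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise FormatError(f"{path.name}: missing required column "
                                  f"'{col}' (found {header})")
        return list(reader)


def _parse_prob(raw: str, path: str, row: int, col: str) -> float:
    try:
        p = float(raw)
    except ValueError:
        raise FormatError(
            f"{path}: row {row}: column '{col}': not a number: {raw!r}")
    if not 0.0 <= p <= 1.0:
        raise FormatError(
            f"{path}: row {row}: column '{col}': probability {p} "
            "outside [0, 1]")
    return p


def read_problem(directory: str | os.PathLike,
                 config: RunConfig | None = None) -> Problem:
    """Load and validate a problem from a dat-file directory.

    The boundary table is optional. The mode is inferred: occurrence-level
    ``prob`` values other than 1 imply species (2D) mode, unit-level ``prob``
    values other than 0 imply threat (1D) mode, neither implies the
    deterministic problem, and both raise :class:`ModeConflictError`.
    """
    config = config or RunConfig()
    d = Path(directory)

    pu_rows = _read_table(d / config.pu_name, ("id", "cost", "status"))
    units = []
    unit_probs_used = False
    for n, row in enumerate(pu_rows, start=2):
        q = 0.0
        if row.get("prob") not in (None, ""):
            q = _parse_prob(row["prob"], config.pu_name, n, "prob")
        if q != 0.0:
            unit_probs_used = True
        try:
            status = UnitStatus(int(row["status"]))
        except ValueError:
            raise FormatError(f"{config.pu_name}: row {n}: bad status "
                              f"code {row['status']!r}")
        units.append(PlanningUnit(id=int(row["id"]), cost=float(row["cost"]),
                                  status=status, loss_probability=q))

    spec_rows = _read_table(d / config.spec_name, ("id", "target", "spf"))
    feats = []
    ptargets: dict[int, tuple[float, float]] = {}
    for n, row in enumerate(spec_rows, start=2):
        fid = int(row["id"])
        p1 = p2 = 0.0
        if row.get("ptarget1d") not in (None, ""):
            p1 = _parse_prob(row["ptarget1d"], config.spec_name, n,
                             "ptarget1d")
        if row.get("ptarget2d") not in (None, ""):
            p2 = _parse_prob(row["ptarget2d"], config.spec_name, n,
                             "ptarget2d")
        ptargets[fid] = (p1, p2)
        feats.append(FeatureRecord(
            id=fid, target=float(row["target"]),
            penalty_factor=float(row["spf"]),
            name=row.get("name") or ""))

    occ_rows = _read_table(d / config.puvspr_name, ("species", "pu", "amount"))
    occs = []
    occ_probs_used = False
    for n, row in enumerate(occ_rows, start=2):
        p = 1.0
        if row.get("prob") not in (None, ""):
            p = _parse_prob(row["prob"], config.puvspr_name, n, "prob")
        if p != 1.0:
            occ_probs_used = True
        occs.append(Occurrence(feature_id=int(row["species"]),
                               unit_id=int(row["pu"]),
                               amount=float(row["amount"]),
                               presence_probability=p))
    occs.sort(key=lambda o: (o.unit_id, o.feature_id))

    bounds = []
    bound_path = d / config.bound_name
    if bound_path.exists():
        for row in _read_table(bound_path, ("id1", "id2", "boundary")):
            bounds.append(BoundarySegment(unit_id_a=int(row["id1"]),
                                          unit_id_b=int(row["id2"]),
                                          length=float(row["boundary"])))

    if unit_probs_used and occ_probs_used:
        raise ModeConflictError(
            f"both {config.pu_name} and {config.puvspr_name} carry "
            "non-default probabilities; threat (1D) and species (2D) modes "
            "are mutually exclusive")
    if occ_probs_used:
        mode = ProblemMode.SPECIES_2D
    elif unit_probs_used:
        mode = ProblemMode.THREAT_1D
    else:
        mode = ProblemMode.DETERMINISTIC

    for f in feats:
        p1, p2 = ptargets[f.id]
        f.probability_target = p1 if mode is ProblemMode.THREAT_1D else p2

    problem = Problem(planning_units=units, features=feats,
                      occurrences=occs, boundaries=bounds, mode=mode)
    violations = validate(problem)
    if violations:
        raise DataValidationError(violations)
    return problem


def _fmt(x: float) -> str:
    """Shortest decimal that round-trips; integers without trailing .0."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def write_problem(problem: Problem, directory: str | os.PathLike,
                  config: RunConfig | None = None) -> list[Path]:
    """Emit the dat-file set for a problem; ``read_problem`` inverts it."""
    config = config or RunConfig()
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written = []

    mode = problem.mode
    pu_path = d / config.pu_name
    with open(pu_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "cost", "status", "prob"])
        for u in problem.planning_units:
            w.writerow([u.id, _fmt(u.cost), int(u.status),
                        _fmt(u.loss_probability)])
    written.append(pu_path)

    spec_path = d / config.spec_name
    with open(spec_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "target", "spf", "ptarget1d", "ptarget2d", "name"])
        for f in problem.features:
            p1 = f.probability_target if mode is ProblemMode.THREAT_1D else 0
            p2 = f.probability_target if mode is ProblemMode.SPECIES_2D else 0
            w.writerow([f.id, _fmt(f.target), _fmt(f.penalty_factor),
                        _fmt(p1), _fmt(p2), f.name])
    written.append(spec_path)

    occ_path = d / config.puvspr_name
    with open(occ_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species", "pu", "amount", "prob"])
        for o in sorted(problem.occurrences,
                        key=lambda o: (o.unit_id, o.feature_id)):
            w.writerow([o.feature_id, o.unit_id, _fmt(o.amount),
                        _fmt(o.presence_probability)])
    written.append(occ_path)

    bound_path = d / config.bound_name
    with open(bound_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id1", "id2", "boundary"])
        for b in problem.boundaries:
            w.writerow([b.unit_id_a, b.unit_id_b, _fmt(b.length)])
    written.append(bound_path)

    return written


_INPUT_KEYS = {
    "BLM": ("boundary_multiplier", float),
    "PROP": ("initial_inclusion_fraction", float),
    "NUMREPS": ("repetitions", int),
    "PROBABILITYWEIGHT": ("probability_weight", float),
    "MISSLEVEL": ("miss_level", float),
    "RANDSEED": ("seed", int),
    "INPUTDIR": ("input_dir", str),
    "OUTPUTDIR": ("output_dir", str),
    "PUNAME": ("pu_name", str),
    "SPECNAME": ("spec_name", str),
    "PUVSPRNAME": ("puvspr_name", str),
    "BOUNDNAME": ("bound_name", str),
    "SHORTFALLSTYLE": ("shortfall_style", str),
    "REPPENALTYSTYLE": ("representation_penalty_style", str),
}


def read_input_dat(path: str | os.PathLike) -> RunConfig:
    """Parse a ``KEY value`` run-parameter file into a :class:`RunConfig`.

    ``NUMITNS``/``NUMTEMP`` configure the annealing schedule and are
    returned through ``RunConfig.schedule``.
    """
    from .solver import AnnealSchedule  # deferred: solver imports model

    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    kv: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise FormatError(f"{path.name}: malformed line {line!r}")
        kv[parts[0].upper()] = parts[1].strip()

    kwargs: dict = {}
    for key, raw in kv.items():
        if key in ("NUMITNS", "NUMTEMP"):
            continue
        if key not in _INPUT_KEYS:
            raise FormatError(f"{path.name}: unrecognized key {key!r}")
        attr, conv = _INPUT_KEYS[key]
        try:
            kwargs[attr] = conv(raw)
        except ValueError:
            raise FormatError(f"{path.name}: key {key}: bad value {raw!r}")

    if "NUMITNS" in kv or "NUMTEMP" in kv:
        try:
            iterations = int(kv.get("NUMITNS", 100_000))
            steps = int(kv.get("NUMTEMP", 100))
        except ValueError as exc:
            raise FormatError(f"{path.name}: {exc}")
        kwargs["schedule"] = AnnealSchedule(iterations=iterations,
                                            temperature_steps=steps)
    try:
        return RunConfig(**kwargs)
    except ConfigurationError as exc:
        raise FormatError(f"{path.name}: {exc}") from exc


def write_input_dat(config: RunConfig, path: str | os.PathLike) -> Path:
    """Emit the run-parameter file for a config (schedule included)."""
    path = Path(path)
    lines = []
    for key, (attr, conv) in _INPUT_KEYS.items():
        val = getattr(config, attr)
        lines.append(f"{key} {_fmt(val) if conv is float else val}")
    if config.schedule is not None:
        lines.append(f"NUMITNS {config.schedule.iterations}")
        lines.append(f"NUMTEMP {config.schedule.temperature_steps}")
    path.write_text("\n".join(lines) + "\n")
    return path


def load_run(input_dat: str | os.PathLike) -> tuple[Problem, RunConfig]:
    """Read ``input.dat`` and the problem directory it points at."""
    input_dat = Path(input_dat)
    config = read_input_dat(input_dat)
    base = input_dat.parent / config.input_dir
    return read_problem(base, config), config
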