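"""Capture probability p_j(x, T_j): will the selected set hold the target?

Under either uncertainty mode each occurrence survives independently with
probability 1 - q_ij, so the amount of feature j held by a reserve x is a
weighted sum of independent Bernoulli variables — a (generalised)
Poisson-binomial. Two engines compute Pr(amount >= T_j):

* ``exact`` — dynamic programming over achievable amounts when the r_ij lie
  on a common grid, otherwise full enumeration of the 2^k outcome space of
  the k selected carriers (k capped). The oracle, and affordable only for
  small reserves.
* ``normal_approx`` — a central-limit approximation: the held amount is
  treated as normal with mean mu_j = sum r_ij x_i (1 - q_ij) and variance
  sigma2_j = sum r_ij^2 x_i q_ij (1 - q_ij); the capture probability is the
  standard-normal upper tail at z_j = (T_j - mu_j) / sigma_j. Fast enough
  to sit inside the annealer's inner loop.

When the variance vanishes (all selected carriers certain one way or the
other) the z-score is undefined and the capture probability degenerates to
1 if mu_j >= T_j and 0 otherwise — the limit of the normal family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np

from .model import CapabilityError, Problem, Solution

__all__ = [
    "FeatureProbabilityState",
    "expected_amount",
    "amount_variance",
    "z_score",
    "normal_upper_tail",
    "approx_capture_probability",
    "exact_capture_probability",
    "poisson_binomial_tail",
]

#: ties at exactly the target count as success; amounts within this slack
#: of the target are treated as meeting it (guards float accumulation)
_TIE_EPS = 1e-9

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class FeatureProbabilityState:
    """Diagnostics of one feature's chance constraint under a selection."""

    feature_id: int
    expected_amount: float
    amount_variance: float
    z: Optional[float]
    capture_probability: float
    engine: str


def _selected_carriers(problem: Problem, solution: Solution,
                       feature_id: int) -> list[tuple[float, float]]:
    """(amount, survival probability) for selected occurrences of a feature."""
    problem.feature(feature_id)
    return [(o.amount, 1.0 - problem.loss_probability(o))
            for o in problem.occurrences
            if o.feature_id == feature_id and solution.is_selected(o.unit_id)]


def expected_amount(problem: Problem, solution: Solution,
                    feature_id: int) -> float:
    """mu_j = sum_i r_ij x_i (1 - q_ij): mean held amount of a feature."""
    return sum(r * s for r, s in
               _selected_carriers(problem, solution, feature_id))


def amount_variance(problem: Problem, solution: Solution,
                    feature_id: int) -> float:
    """sigma2_j = sum_i r_ij^2 x_i q_ij (1 - q_ij): variance of held amount."""
    return sum(r * r * s * (1.0 - s) for r, s in
               _selected_carriers(problem, solution, feature_id))


def z_score(target: float, expected: float,
            variance: float) -> Optional[float]:
    """Standard score of the target; None when the variance is zero."""
    if variance < 0:
        raise ValueError(f"variance must be >= 0, got {variance}")
    if variance == 0.0:
        return None
    return (target - expected) / math.sqrt(variance)


def normal_upper_tail(z: float) -> float:
    """Pr(Z >= z) for standard normal Z, via the complementary error
    function (the PrZUT percentile lookup)."""
    if not math.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    return 0.5 * math.erfc(z / _SQRT2)


def approx_capture_probability(problem: Problem, solution: Solution,
                               feature_id: int) -> FeatureProbabilityState:
    """Normal (CLT) approximation of the capture probability."""
    mu = expected_amount(problem, solution, feature_id)
    var = amount_variance(problem, solution, feature_id)
    target = problem.feature(feature_id).target
    z = z_score(target, mu, var)
    if z is None:
        p = 1.0 if mu >= target - _TIE_EPS else 0.0
    else:
        p = normal_upper_tail(z)
    return FeatureProbabilityState(
        feature_id=feature_id, expected_amount=mu, amount_variance=var,
        z=z, capture_probability=p, engine="normal_approx")


def _common_grid(amounts: list[float]) -> Optional[float]:
    """Largest step g with every amount an integer multiple of g, if the
    amounts are (near-)rational with small denominators; None otherwise."""
    fracs = []
    for a in amounts:
        f = Fraction(a).limit_denominator(10**6)
        if abs(float(f) - a) > 1e-9 * max(1.0, abs(a)):
            return None
        fracs.append(f)
    # gcd of fractions: gcd(numerators) / lcm(denominators)
    num = fracs[0].numerator
    den = fracs[0].denominator
    for f in fracs[1:]:
        num = math.gcd(num, f.numerator)
        den = den * f.denominator // math.gcd(den, f.denominator)
    return num / den if num else None


def poisson_binomial_tail(carriers: list[tuple[float, float]], target: float,
                          enumeration_limit: int = 20) -> float:
    """Pr(sum r_i B_i >= target) for independent B_i ~ Bernoulli(s_i).

    ``carriers`` is a list of (amount r_i, survival probability s_i).
    Certain carriers (s = 0 or 1) are folded out first; the residual
    problem is solved by grid dynamic programming when the amounts share a
    common step, else by enumerating the 2^k outcomes (k capped at
    ``enumeration_limit``).
    """
    if target <= _TIE_EPS:
        return 1.0
    base = 0.0
    random_part: list[tuple[float, float]] = []
    for r, s in carriers:
        if s >= 1.0:
            base += r
        elif s > 0.0:
            random_part.append((r, s))
    if base >= target - _TIE_EPS:
        return 1.0
    if not random_part:
        return 0.0

    need = target - base
    amounts = [r for r, _ in random_part]
    grid = _common_grid(amounts)
    k = len(random_part)

    if grid is not None:
        counts = [round(r / grid) for r in amounts]
        total = sum(counts)
        if total + 1 <= 5_000_000:
            dist = np.zeros(total + 1)
            dist[0] = 1.0
            top = 0
            for c, (_, s) in zip(counts, random_part):
                nxt = dist[:top + c + 1] * (1.0 - s)
                nxt[c:top + c + 1] += dist[:top + 1] * s
                dist[:top + c + 1] = nxt
                top += c
            # smallest grid count meeting the residual target
            kmin = math.ceil(need / grid - _TIE_EPS)
            if kmin <= 0:
                return 1.0
            if kmin > total:
                return 0.0
            return float(dist[kmin:].sum())

    if k > enumeration_limit:
        raise CapabilityError(
            f"{k} uncertain carriers exceed the exact-engine limit of "
            f"{enumeration_limit} and the amounts share no common grid; "
            "use the normal_approx engine")

    # dict convolution == pruned enumeration of the 2^k outcome space
    dist_d: dict[float, float] = {0.0: 1.0}
    tail = 0.0
    for r, s in random_part:
        nxt_d: dict[float, float] = {}
        for amt, pr in dist_d.items():
            hit = round(amt + r, 9)
            if hit >= need - _TIE_EPS:
                tail += pr * s
            else:
                nxt_d[hit] = nxt_d.get(hit, 0.0) + pr * s
            nxt_d[amt] = nxt_d.get(amt, 0.0) + pr * (1.0 - s)
        dist_d = nxt_d
    return min(1.0, tail)


def exact_capture_probability(problem: Problem, solution: Solution,
                              feature_id: int,
                              enumeration_limit: int = 20) -> float:
    """Exact Pr(held amount >= T_j) over the selected carriers.

    Ties at exactly the target count as success. Raises
    :class:`CapabilityError` when the instance is too large for exact
    computation (no common amount grid and more uncertain carriers than
    ``enumeration_limit``).
    """
    carriers = _selected_carriers(problem, solution, feature_id)
    target = problem.feature(feature_id).target
    return poisson_binomial_tail(carriers, target,
                                 enumeration_limit=enumeration_limit)


def exact_probability_state(problem: Problem, solution: Solution,
                            feature_id: int,
                            enumeration_limit: int = 20
                            ) -> FeatureProbabilityState:
    """Full diagnostics with the exact engine's capture probability."""
    mu = expected_amount(problem, solution, feature_id)
    var = amount_variance(problem, solution, feature_id)
    target = problem.feature(feature_id).target
    p = exact_capture_probability(problem, solution, feature_id,
                                  enumeration_limit=enumeration_limit)
    return FeatureProbabilityState(
        feature_id=feature_id, expected_amount=mu, amount_variance=var,
        z=z_score(target, mu, var), capture_probability=p, engine="exact")
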