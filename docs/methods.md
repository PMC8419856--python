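# Methods

## Model

`marprob` solves the chance-constrained minimum-set reserve problem. A
landscape is divided into N planning units; unit *i* has cost `c_i`, a lock
status, and may share boundary length `v_ih` with neighbours (a segment with
both ends on the same unit is an exposed outer edge). Feature *j* occurs in
a sparse set of units with amount `r_ij`; it carries a representation target
`T_j`, a penalty factor `F_j` and a probability target `P_j ∈ [0,1]`.

Uncertainty is a per-occurrence absence/loss probability `q_ij`, supplied in
one of two mutually exclusive ways:

* **species mode (2D)** — each occurrence row carries its own existence
  probability `1 − q_ij` (SDM output, habitat-map accuracy);
* **threat mode (1D)** — each *unit* carries one loss probability `q_i`
  applying to all its features (catastrophe, succession, degradation).

Occurrences survive independently. The amount of feature *j* held by a
selection `x` is then a sum of independent scaled Bernoulli variables, and
the capture probability is `p_j(x,T_j) = Pr(Σ_i r_ij x_i B_i ≥ T_j)` with
`B_i ~ Bernoulli(1 − q_ij)`. Independence is a modelling assumption, not a
fact about landscapes: spatial autocorrelation of threats inflates the
estimated probabilities, and covariation between units is deliberately out
of scope.

## Objective

The solver minimises

```
Σ_i c_i x_i                                   cost
+ b · open boundary length                    compactness (BLM)
+ y · Σ_j F_j R_j · rep_shortfall_j           representation penalty
+ w · Σ_j F_j R_j · prob_shortfall_j          probability penalty
```

* The boundary term counts each stored segment once when it separates a
  selected from an unselected unit; exposed self-edges count whenever their
  unit is selected.
* `R_j` is the representation cost of feature *j*: the cost of the greedy
  cheapest set of carriers (ascending cost-per-amount, unit id breaking
  ties, locked-out units excluded) that reaches `T_j`. If the target is
  unreachable, all carriers are used and a warning is raised. `R_j` scales
  both penalties so that a missed feature is worth roughly what it would
  cost to fix.
* `rep_shortfall_j` is, by configuration, a step indicator `[held_j < T_j]`
  or the proportional shortfall `max(0, 1 − held_j/T_j)`. A target held
  exactly counts as met — the penalty formulation's Heaviside is aligned
  with the `≥` of the constraint it replaces, so an exactly-met target is
  never charged.
* `prob_shortfall_j` is `max(0, P_j − p_j)` (`raw` style) or that divided by
  `P_j` (`normalized` style, the default, which makes missing a 0.5 target
  by 0.1 as expensive as missing a 0.9 target by 0.18). Features with
  `P_j = 0` carry no chance constraint, which also keeps the normalized
  style well defined.
* The representation term keeps its own weight `y` even though the
  chance-constrained formulation could in principle drop it: without it a
  feature with `P_j = 0` would be entirely unconstrained. Setting `y = 0`
  recovers the purely probabilistic objective; setting all probabilities
  to 1 makes the probability term vanish and recovers the classic
  deterministic objective.

## Capture-probability engines

**Exact (Poisson-binomial).** Certain carriers (`q = 0` or `1`) are folded
out first. If the remaining amounts lie on a common grid (detected by
rationalising each amount with denominator ≤ 1e6 and taking the fraction
gcd), the tail is computed by dynamic programming over achievable grid
amounts (numpy convolution, up to 5e6 states). Otherwise the 2^k outcome
space of the k uncertain carriers is enumerated through a pruned dict
convolution, with k capped at 20 (a `CapabilityError` beyond that advises
the normal engine). Ties at exactly the target count as success, and a 1e-9
slack absorbs float accumulation. Against a brute-force 2^k oracle the
engine agrees to 1e-12 on random instances with k ≤ 12.

**Normal approximation (CLT).** The held amount is treated as normal with
mean `μ_j = Σ r_ij x_i (1 − q_ij)` and variance
`σ²_j = Σ r²_ij x_i q_ij (1 − q_ij)`;
`p_j = Pr(Z ≥ z_j)` with `z_j = (T_j − μ_j)/σ_j`, evaluated through the
complementary error function rather than table lookup. The variance
expression is used as a *variance* (its square root standardises the
score); treating it as a standard deviation would make the percentile
meaningless. When `σ²_j = 0` the z-score is undefined and the probability
degenerates to 1 if `μ_j ≥ T_j`, else 0 — the limit of the normal family.
The approximation is deliberately crude on tiny reserves (it returns 0.5
where the exact engine returns 0.75 on a two-coin-flip example, since
`μ = T` centres the normal on the target) but converges for realistic
reserve sizes: on homogeneous 50-carrier instances it is within 0.05 of
exact across presence probabilities 0.2–0.8. The annealer therefore
defaults to the normal engine; the exact engine is the reporting and
small-problem oracle.

## Solvers

**Simulated annealing.** Uniform single-unit flips among unlocked units;
delta accepted when negative, else with probability `exp(−d/T)`. The
temperature decays geometrically over `temperature_steps` steps spanning
`iterations` total flips (defaults 100 and 1e5). The initial temperature
defaults to the 90th percentile of |delta| over 100 sampled flips from the
starting state — large enough to accept most early moves, small enough to
be problem-scaled — and the final temperature to 1e-4 of it; both are
overridable. The best state ever visited is returned. Starting reserves
include each free unit independently with probability `PROP`
(`initial_inclusion_fraction`); locked-in and initially-selected units
always start selected, locked-out units never.

Flips are evaluated incrementally: the evaluator keeps running cost,
boundary, held amount, mean and variance per feature, so one flip costs
O(unit degree + features carried), with only affected features re-scored.
The incremental delta agrees with full re-evaluation to 1e-9 over long
random flip sequences.

**Improvement.** Steepest-descent single-flip passes until no flip reduces
the objective; used to polish each annealing repetition.

**Exhaustive search.** For ≤ 20 free units, full enumeration gives the
certified optimum (ties broken toward fewer units, then lexicographic id
order). It is the solver-correctness oracle: on seeded 10-unit instances,
best-of-10 annealing runs reach the exhaustive optimum in ≥ 90% of trials.

**Batch runs.** `run_batch` derives one child seed per repetition from the
master seed (numpy `SeedSequence.spawn`), anneals and improves each, and
aggregates per-unit selection frequencies. Identical (problem, config,
seed) triples give bit-identical results.

## Synthetic data

The fixture module generates two kinds of instances.

*Worked examples* — the three documented four-unit illustrations (one or
two species on units p2–p4 with fixed occurrence probabilities, all targets
1). Units carry cost 1 and no boundary segments, so the probability
arithmetic is the only active term.

*Random landscapes* — rectangular grids with rook adjacency (interior
segments of length 1; edge units carry a self-segment equal to their number
of exposed outer edges), lognormal costs (log-sd 0.5 around cost 1),
features occupying a seeded random 30% of units with amount 1, and
Beta(4, 2) probabilities (mean 2/3 — moderately reliable occurrences,
typical of usable SDM outputs). Feature targets default to half of each
feature's total amount, rounded up, so targets are always reachable.
Occupancy is spatially uniform: the generator does not emulate the spatial
autocorrelation, rarity structure or cost-threat correlation of real
landscapes, so solver tests certify optimisation correctness, not
ecological realism. Test and oracle problems use 10–25 units so exhaustive
enumeration stays affordable; the engines themselves have no such limit.

## File dialect and reports

Comma-separated tables with lower-case headers (`pu.dat`: id, cost, status,
prob; `spec.dat`: id, target, spf, ptarget1d, ptarget2d, name;
`puvspr.dat`: species, pu, amount, prob; `bound.dat`: id1, id2, boundary),
plus an `input.dat` of `KEY value` pairs. Floats are written in shortest
round-trip form, so write → read is field-exact. Mode is inferred from
which probability columns carry non-default values; populating both is an
error. Status codes: 0 available, 1 available-initially-selected, 2 locked
in, 3 locked out.

The missing-values report extends the classic per-feature table with eight
chance-constraint columns — probability mode, `P_j`, `p_j`, `μ_j`,
variance, z-score, probability shortfall and a met flag (true whenever
`P_j = 0`). This column set is this package's reconstruction of the
extended report; the historical field list was not available, so the
quantities the approximation itself computes were chosen.

## Numerical choices and limitations

* Ties: targets and probability targets met exactly count as met (1e-9
  slack); exhaustive-search ties prefer smaller, lexicographically earlier
  reserves; greedy representation-cost ties prefer lower unit ids.
* `MISSLEVEL` is parsed for compatibility but the met flags in reports use
  the full target.
* The probability penalty is recomputed per affected feature per flip; with
  the exact engine inside the annealer this costs a Poisson-binomial solve
  per flip and is only sensible for small instances.
* No GIS ingestion (boundary lengths must be precomputed), no multi-zone
  planning, no asymmetric connectivity, no covariation between units.
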