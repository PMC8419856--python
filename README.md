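# marprob

Chance-constrained minimum-set reserve selection: a Python implementation
of Marxan-style protected-area design in which every conservation feature
must meet its representation target **with a user-specified probability**,
given probabilistic occurrence or threat data.

## The problem

Classic minimum-set reserve selection chooses planning units `x_i ∈ {0,1}`
to minimise

```
Σ_i c_i x_i  +  b Σ_i Σ_h x_i (1 − x_h) v_ih
```

subject to `Σ_i r_ij x_i ≥ T_j` for every feature `j` (costs `c_i`, boundary
lengths `v_ih`, occurrence amounts `r_ij`, targets `T_j`). Real data are
uncertain: a species-distribution model only gives a *probability* that a
feature is present, and threats (bleaching, fire, degradation) may remove a
site's features after protection. `marprob` replaces the deterministic
constraint with a chance constraint

```
p_j(x, T_j) ≥ P_j        for every feature j,
```

where `p_j(x, T_j)` is the probability that the selected set actually holds
at least `T_j` of feature `j` when each occurrence survives independently
with probability `1 − q_ij`. Uncertainty is supplied either per occurrence
(*species mode*, `q_ij` from SDM outputs or map accuracy) or per planning
unit (*threat mode*, a single loss probability for all features at a site).
Both constraints are folded into a penalty objective

```
Σ c_i x_i + b·(boundary) + y Σ_j F_j R_j·rep_shortfall_j
                         + w Σ_j F_j R_j·max(0, P_j − p_j)/P_j
```

minimised by simulated annealing. `p_j` comes from either an **exact
Poisson-binomial engine** (dynamic programming / enumeration over the
selected carriers — the oracle, used for reports and small problems) or a
**normal (CLT) approximation** `p_j = Pr(Z ≥ (T_j − μ_j)/σ_j)` with
`μ_j = Σ r_ij x_i (1−q_ij)` and `σ²_j = Σ r²_ij x_i q_ij (1−q_ij)`, which is
fast enough for the annealer's inner loop.

The package reads and writes the community dat-file dialect
(`pu.dat`, `spec.dat`, `puvspr.dat`, `bound.dat`, `input.dat`) with the
probability extensions (`prob` columns, `ptarget1d`/`ptarget2d`), and is
aimed at conservation planners and researchers who want reproducible,
scriptable chance-constrained prioritisation.

## Worked example

The smallest interesting instance: one species occurring in two of four
units with probability 0.5 each, target 1 occurrence, probability target
0.8.

```python
import marprob as mp

problem = mp.toy_problem(2)          # 4 units, species 2 at p2/p3, P = 0.8
one  = mp.Solution.from_ids(problem, [2])
both = mp.Solution.from_ids(problem, [2, 3])

print(mp.exact_capture_probability(problem, one, 1))    # 0.5
print(mp.exact_capture_probability(problem, both, 1))   # 0.75

cfg = mp.RunConfig(probability_weight=50.0, probability_engine="exact",
                   representation_weight=0.0)
solution, breakdown = mp.solve_exact(problem, cfg)
print(solution.selected_ids)                            # [2, 3]
print(round(breakdown.probability_penalty_term, 4))     # 3.125
```

A single unit captures the species with probability 0.5 and two units with
`1 − 0.5² = 0.75` — still below the 0.8 target, so even the optimal reserve
carries a residual probability penalty (`50 × (0.8 − 0.75)/0.8 = 3.125`);
a deterministic treatment of the same data would have called one unit
sufficient. Larger problems go through `run_batch` /
`anneal` + `improve`, or the CLI:

```sh
marprob generate --spec landscape.json --out ./data
marprob solve --input ./input.dat --reps 10 --seed 1 --out ./output
marprob validate --input ./data
```

`solve` writes one `output_rNNNN.csv` selection per repetition, the best
run, a selection-frequency table (`output_ssoln.csv`) and a per-feature
missing-values report (`output_mv.csv`) with held amount, capture
probability, z-score and shortfalls.

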