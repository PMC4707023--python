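# Methods

## Model and representation

A program is a function ℝᵖ → ℝ built from the binary arithmetic primitives
{+, −, ×, ÷ₚ}, input variables and ephemeral constants.  Its *semantics* is
the vector of its outputs on the training instances (a parallel vector is
maintained for the held-out test instances, so test fitness is available
every generation without ever building a tree).  Fitness is RMSE against
the targets; lower is better.

The geometric semantic operators act on semantics coordinate-wise:

- crossover: `child(i) = p1(i)·r(i) + (1 − r(i))·p2(i)` with one random
  tree `r` whose outputs lie in [0, 1].  The child is coordinate-wise
  convex between its parents (property-tested).
- mutation: `child(i) = t(i) + ms·(r1(i) − r2(i))` with two distinct [0, 1]
  random trees; every coordinate moves by at most `ms` (property-tested).

Individuals are stored as semantics + exact size + a lineage record
(operator kind, parent references, random-tree references, `ms`).  Only
generation-0 trees and random trees exist as syntax, in an append-only
pedigree store whose entries are never mutated.  This gives O(ng) evolution
cost and O(g) unseen-instance evaluation; `reconstruct_expression` unfolds
the lineage into the full tree on demand and refuses — reporting the exact
size — above the `size_guard` (default 2¹⁷ nodes, the size of a depth-17
tree over binary primitives; Koza's depth limit translated to a node
budget, used as the boundary between manageable and unmanageable models).

### Exact size accounting

Crossover builds `(T1 · TR) + ((1 − TR) · T2)`: one `+`, two `×`, one `−`
and the literal 1, i.e. exactly **5** nodes beyond the copies of T1, T2 and
the *two* occurrences of TR (counted twice).  Mutation builds
`T + ms·(TR1 − TR2)`: one `+`, one `×`, the `ms` constant and one `−`,
i.e. exactly **4** extra nodes (`ms` is one node, not a subtree).  Sizes
propagate through this recurrence as exact Python integers — final sizes
beyond 10⁴⁰ are routine and exceed 64-bit float integer precision, so no
float ever touches them.  Reconstruction counts shared subtrees with
multiplicity, so `node_count(reconstruct(ind)) == ind.size` exactly; this
identity is asserted in the tests for lineages up to six operator
applications and on evolved 50-generation lineages.

The population-level consequence is the average-size bound

    S(t) = p_xo·(2·S(t−1) + 2·B + 5) + p_m·(S(t−1) + 2·B + 4) + p_r·S(t−1)

with B the per-random-tree node budget.  Two conventions are provided:
`pow2` (B = 2ᴰ, the form in which the recurrence is usually printed for
binary primitives) and `strict` (B = 2ᴰ⁺¹ − 1, the true node count of a
full depth-D binary tree).  The wrapped random trees used here have a hard
cap of 2ᴰ⁺¹ nodes (full tree + wrapper), so the simulation-domination test
passes that cap explicitly.  Domination of the simulated mean by the bound
is *sure* only when the event mix is deterministic (pure crossover or pure
mutation) and the initial population has equal sizes — with mixed rates the
bound holds in expectation, and a lucky run can momentarily exceed it —
so the test uses the deterministic mixes.

### Elitist replacement

A crossover child is accepted iff its training RMSE is strictly lower than
*both* parents'; a mutation child iff strictly lower than its parent's.
Otherwise a parent is copied: for crossover, the better parent by default
(`surviving_parent_policy="best"`), or a uniformly random one
(`"random"`); the choice is reported to have a very weak effect.  Ties
reject the child — keeping the smaller model is exactly the point of the
rule.  Acceptance reads training fitness only; test semantics are tracked
but never influence any decision.  Success counters (the same strict
comparisons) are recorded in both systems; standard GSGP records them
without acting on them, which is what the success-rate study instruments.

## The generational loop

Each of the n offspring slots draws exactly one event with probabilities
(p_xo, p_m, p_r) summing to 1 — operators are mutually exclusive per slot,
not chained.  Parents are chosen by tournament selection (k distinct
individuals drawn uniformly without replacement; ties broken by smaller
size, then earlier id).  Random trees are generated fresh per event and
stored in the pedigree.  With `best_survives` (default on) the incumbent
best is copied unchanged over the worst offspring slot, so best-fitness
curves are non-increasing in both systems.  A single seeded PCG64 generator
drives everything: same seed, data and config give a bit-identical trace.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `population_size` | 50 | desk-scale default; the full protocol used larger populations |
| `generations` | 200 | desk-scale analogue of the 1000-generation benchmark protocol |
| `p_crossover, p_mutation, p_reproduction` | 0.7, 0.25, 0.05 | explicit configuration; no canonical published values exist for this setting |
| `mutation_step` (ms) | 1.0 | per-coordinate perturbation radius; study values 0.01, 0.1, 1, with 1 reported best on all five benchmarks |
| `tournament_size` | 4 | standard GP default; any selection scheme can be substituted |
| `elitist_replacement` | on | the proposed system; off = standard GSGP |
| `surviving_parent_policy` | best | weakly influential; both options implemented |
| `best_survives` | on | makes fitness curves non-increasing, as reported |
| `random_tree_max_depth` (D) | 6 | depth budget of operator random trees; enters the size bound |
| `random_tree_method` | grow | full also available |
| init depths | ramped half-and-half, 2–6 | Koza-standard initialisation choice |
| `constant_range` | [−1, 1] | ephemeral constants |
| `size_guard` | 2¹⁷ | reconstruction refusal threshold |

## Numerical choices

- **Protected division** returns 1 wherever |denominator| ≤ 1e-6, so
  evaluation is finite on finite input.  Configurable primitive set.
- **[0, 1] codomain** of random trees is enforced by composing the raw tree
  with the logistic 1/(1+e⁻ᵗ) (`scipy.special.expit`), counted as one
  node; this matches the reference implementation style and preserves
  functional diversity.  The logistic is a fourth node kind (unary) since
  it cannot be expressed with binary arithmetic primitives.
- "Better" is strict `<` on training RMSE everywhere (acceptance, success
  counters); equal-fitness ties go to the smaller model, then the earlier
  id, making every comparison a total order and runs reproducible.
- Train/test splits take `round(train_fraction · n)` rows uniformly without
  replacement from a seeded permutation.
- CSV round trips are bit-exact (`%.17g` on write, round-trip float parsing
  on read).
- Mann-Whitney: exact null distribution when min(n, m) ≤ 8 with no ties,
  normal approximation with tie correction otherwise; Shapiro-Wilk p-values
  are recorded as justification for using a rank test but never branch the
  analysis — the two-sided U test at α = 0.1 always decides.
- Per-run experiment seeds are `base_seed + run_index`, so the two systems
  see paired data partitions and reruns are byte-identical.

## Synthetic data: what it emulates, and what a green test establishes

The five presets reproduce the *shapes* of the benchmark datasets
(260×241, 234×626, 131×626, 1030×8, 6000×19) with features uniform in
[−1, 1], a hidden nonlinear ground truth over the first 4–6 variables
(products, a smooth rational term), all other features pure decoys, and
Gaussian noise.  Targets are placed on each endpoint's natural units —
percentages for oral bioavailability and plasma protein binding, mg/kg
(thousands) for LD50, MPa for concrete strength, a clinical score for the
Parkinson voice data — because the mutation steps of the study are
*absolute*: on unit-scale targets ms = 1 would dwarf the whole target range
and mutation would essentially never improve fitness, contradicting the
observed 20–80% success rates.  Noise SD is 1/20 of the target scale factor
(≈10% of signal SD), a realistic noise floor for such assays.

What the synthetic world does **not** emulate: correlated molecular
descriptors, heavy-tailed feature distributions, label noise structure, or
ground truths outside the engine's own primitive set.  A green
direction-of-effect test therefore establishes that *given data of this
shape and scale*, elitist replacement yields comparable training fitness
with drastically smaller models; it does not certify the magnitudes
reported on the proprietary benchmarks, which are not redistributable and
were run at 30×1000-generation scale.

## Known limitations

- No simplification or algebraic compression of reconstructed expressions.
- Reconstruction of models near the 2¹⁷-node guard is possible but slow by
  design; the guard exists precisely because such models are unusable.
- The success-rate levels on synthetic data (mutation ≈ 50%, crossover
  ≈ 13%) reproduce the ordering and regime of the benchmark study but not
  its exact percentages, which depend on the real datasets.
- Population-level size statistics use exact integers, but `mean_size`
  degrades to `inf` past 10³⁰⁰ (floats cannot carry it); `best_size` and
  `median_size` stay exact.
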