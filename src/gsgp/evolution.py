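"""Generational loop for standard and elitist geometric semantic GP.

Both systems share one loop.  Each offspring slot draws exactly one event —
crossover, mutation, or reproduction — with probabilities (p_xo, p_m, p_r)
summing to one.  Success counters (a crossover child strictly fitter than
both parents; a mutation child strictly fitter than its parent) are recorded
in *both* systems; only the elitist system acts on them, copying a parent
into the new population whenever the child fails the test.  "Better" means
strictly lower training RMSE; ties reject the child, which keeps the smaller
model.

Selection is tournament selection (the usual choice when none is dictated);
ties inside a tournament are broken by smaller size, then lower id, so runs
are bit-for-bit reproducible from the seed.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np

from .expressions import PrimitiveSet, RandomTreeSpec, evaluate_tree, generate_random_tree
from .metrics import rmse
from .semantics import (
    Individual,
    PedigreeStore,
    StoredTree,
    make_genesis_individual,
    reproduce,
    semantic_crossover,
    semantic_mutation,
)

__all__ = [
    "RunConfig",
    "GenerationStats",
    "RunTrace",
    "rmse",
    "tournament_select",
    "elitist_accept_crossover",
    "elitist_accept_mutation",
    "step_generation",
    "run_evolution",
]


@dataclass(frozen=True)
class RunConfig:
    """Every knob of one evolutionary run.

    Operator rates default to p_xo=0.7, p_m=0.25, p_r=0.05 and the
    tournament to k=4; these are explicit configuration, not dictated
    values.  The mutation step defaults to 1, the value reported to give
    the best fitness on all the study problems.
    """

    population_size: int = 50
    generations: int = 200
    p_crossover: float = 0.7
    p_mutation: float = 0.25
    p_reproduction: float = 0.05
    mutation_step: float = 1.0
    tournament_size: int = 4
    elitist_replacement: bool = True
    surviving_parent_policy: str = "best"
    best_survives: bool = True
    seed: int = 0
    random_tree_max_depth: int = 6
    random_tree_method: str = "grow"
    init_min_depth: int = 2
    init_max_depth: int = 6
    operators: tuple[str, ...] = ("add", "sub", "mul", "div")
    constant_range: tuple[float, float] = (-1.0, 1.0)
    size_guard: int = 2**17

    def validate(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        total = self.p_crossover + self.p_mutation + self.p_reproduction
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"operator probabilities sum to {total}, not 1")
        if min(self.p_crossover, self.p_mutation, self.p_reproduction) < 0:
            raise ValueError("operator probabilities must be nonnegative")
        if self.mutation_step <= 0:
            raise ValueError("mutation_step must be positive")
        if not 1 <= self.tournament_size <= self.population_size:
            raise ValueError("tournament_size must be in [1, population_size]")
        if self.surviving_parent_policy not in ("best", "random"):
            raise ValueError("surviving_parent_policy must be 'best' or 'random'")
        if not 0 <= self.init_min_depth <= self.init_max_depth:
            raise ValueError("initial depth range is invalid")
        # delegate the rest
        self.random_tree_spec  # noqa: B018

    @property
    def random_tree_spec(self) -> RandomTreeSpec:
        return RandomTreeSpec(
            max_depth=self.random_tree_max_depth,
            method=self.random_tree_method,
            unit_interval_wrap=True,
        )


@dataclass(frozen=True)
class GenerationStats:
    """Per-generation summary: best fitnesses, sizes, operator counters."""

    generation: int
    best_train_fitness: float
    best_test_fitness: float | None
    best_size: int
    median_size: int | float
    mean_size: float
    crossover_events: int = 0
    crossover_successes: int = 0
    mutation_events: int = 0
    mutation_successes: int = 0


@dataclass
class RunTrace:
    """Config snapshot, ordered per-generation stats, and the pedigree."""

    config: RunConfig
    stats: list[GenerationStats]
    best_id: int
    store: PedigreeStore

    @property
    def best(self) -> Individual:
        return self.store.individual(self.best_id)

    def to_frame(self):
        """Per-generation statistics as a DataFrame (CSV column contract)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": [s.generation for s in self.stats],
                "best_train": [s.best_train_fitness for s in self.stats],
                "best_test": [s.best_test_fitness for s in self.stats],
                "best_size": [s.best_size for s in self.stats],
                "median_size": [float(s.median_size) for s in self.stats],
                "xo_events": [s.crossover_events for s in self.stats],
                "xo_successes": [s.crossover_successes for s in self.stats],
                "mut_events": [s.mutation_events for s in self.stats],
                "mut_successes": [s.mutation_successes for s in self.stats],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class _Context:
    """Data and pools threaded through one run."""

    prims: PrimitiveSet
    tree_spec: RandomTreeSpec
    X_train: np.ndarray
    y_train: np.ndarray
    store: PedigreeStore
    X_test: np.ndarray | None = None
    y_test: np.ndarray | None = None
    X_all: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.X_test is None:
            self.X_all = self.X_train
        else:
            self.X_all = np.vstack([self.X_train, self.X_test])


def _fitness_key(ind: Individual):
    # strict ordering: fitness, then smaller model, then insertion order
    return (ind.train_fitness, ind.size, ind.id)


def tournament_select(
    pop: list[Individual], k: int, rng: np.random.Generator
) -> Individual:
    """Best of ``k`` distinct individuals drawn uniformly.

    Drawing without replacement makes a full-population tournament
    deterministic (always the global best); ties on fitness go to the
    smaller model, then to the earlier id.
    """
    if not pop:
        raise ValueError("cannot select from an empty population")
    if not 1 <= k <= len(pop):
        raise ValueError("tournament size must be in [1, len(pop)]")
    idx = rng.choice(len(pop), size=k, replace=False)
    return min((pop[i] for i in idx), key=_fitness_key)


def elitist_accept_crossover(child: Individual, p1: Individual, p2: Individual) -> bool:
    """Accept iff the child is strictly fitter (train RMSE) than BOTH parents."""
    return child.train_fitness < min(p1.train_fitness, p2.train_fitness)


def elitist_accept_mutation(child: Individual, parent: Individual) -> bool:
    """Accept iff the child is strictly fitter (train RMSE) than its parent."""
    return child.train_fitness < parent.train_fitness


def _fresh_random_tree(ctx: _Context, rng: np.random.Generator) -> StoredTree:
    """Generate a fresh [0, 1]-wrapped random tree and cache its semantics."""
    tree = generate_random_tree(ctx.prims, ctx.tree_spec, rng)
    values = evaluate_tree(tree, ctx.X_all)
    n_train = ctx.X_train.shape[0]
    test_values = None if ctx.X_test is None else values[n_train:]
    return ctx.store.add_tree(tree, values[:n_train], test_values)


def _population_stats(
    generation: int,
    pop: list[Individual],
    xo_events: int = 0,
    xo_successes: int = 0,
    mut_events: int = 0,
    mut_successes: int = 0,
) -> GenerationStats:
    best = min(pop, key=_fitness_key)
    sizes = [ind.size for ind in pop]
    total = sum(sizes)
    # sizes are exact big integers; the float mean may overflow late in a run
    mean_size = total / len(sizes) if total < 10**300 else float("inf")
    return GenerationStats(
        generation=generation,
        best_train_fitness=best.train_fitness,
        best_test_fitness=best.test_fitness,
        best_size=best.size,
        median_size=statistics.median(sizes),
        mean_size=float(mean_size),
        crossover_events=xo_events,
        crossover_successes=xo_successes,
        mutation_events=mut_events,
        mutation_successes=mut_successes,
    )


def _init_population(
    config: RunConfig, ctx: _Context, rng: np.random.Generator
) -> list[Individual]:
    """Ramped half-and-half initial population (raw trees, not wrapped)."""
    span = config.init_max_depth - config.init_min_depth + 1
    pop = []
    for i in range(config.population_size):
        spec = RandomTreeSpec(
            max_depth=config.init_min_depth + (i // 2) % span,
            method="full" if i % 2 else "grow",
            unit_interval_wrap=False,
        )
        tree = generate_random_tree(ctx.prims, spec, rng)
        pop.append(
            make_genesis_individual(
                tree, ctx.X_train, ctx.y_train, ctx.store, ctx.X_test, ctx.y_test
            )
        )
    return pop


def step_generation(
    pop: list[Individual],
    config: RunConfig,
    ctx: _Context,
    rng: np.random.Generator,
    generation: int,
) -> tuple[list[Individual], GenerationStats]:
    """Build the next population of ``n`` offspring slots.

    Every slot draws one mutually exclusive event.  Success counters are
    updated in both systems; the elitist system additionally replaces a
    failed child by a surviving parent (the best of the two, or a random
    one, per the configured policy).  When ``best_survives`` is set, the
    incumbent best is copied unchanged over the worst offspring slot.
    """
    new_pop: list[Individual] = []
    xo_events = xo_successes = mut_events = mut_successes = 0
    p_xo, p_m = config.p_crossover, config.p_mutation

    for _ in range(config.population_size):
        u = rng.random()
        if u < p_xo:
            p1 = tournament_select(pop, config.tournament_size, rng)
            p2 = tournament_select(pop, config.tournament_size, rng)
            r = _fresh_random_tree(ctx, rng)
            child = semantic_crossover(p1, p2, r, ctx.store, ctx.y_train, ctx.y_test)
            xo_events += 1
            accepted = elitist_accept_crossover(child, p1, p2)
            if accepted:
                xo_successes += 1
            if accepted or not config.elitist_replacement:
                new_pop.append(child)
            elif config.surviving_parent_policy == "best":
                new_pop.append(min(p1, p2, key=_fitness_key))
            else:
                new_pop.append(p1 if rng.random() < 0.5 else p2)
        elif u < p_xo + p_m:
            parent = tournament_select(pop, config.tournament_size, rng)
            r1 = _fresh_random_tree(ctx, rng)
            r2 = _fresh_random_tree(ctx, rng)
            child = semantic_mutation(
                parent, r1, r2, config.mutation_step, ctx.store, ctx.y_train, ctx.y_test
            )
            mut_events += 1
            accepted = elitist_accept_mutation(child, parent)
            if accepted:
                mut_successes += 1
            if accepted or not config.elitist_replacement:
                new_pop.append(child)
            else:
                new_pop.append(parent)
        else:
            parent = tournament_select(pop, config.tournament_size, rng)
            new_pop.append(reproduce(parent, ctx.store))

    if config.best_survives:
        incumbent = min(pop, key=_fitness_key)
        worst_slot = max(range(len(new_pop)), key=lambda i: _fitness_key(new_pop[i]))
        new_pop[worst_slot] = incumbent

    stats = _population_stats(
        generation, new_pop, xo_events, xo_successes, mut_events, mut_successes
    )
    return new_pop, stats


def run_evolution_arrays(
    config: RunConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
) -> RunTrace:
    """Run one seeded evolution on raw arrays and return the full trace."""
    config.validate()
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] != y_train.shape[0]:
        raise ValueError("X_train must be 2-D with one target per row")
    rng = np.random.default_rng(config.seed)
    ctx = _Context(
        prims=PrimitiveSet(
            n_features=X_train.shape[1],
            binary_ops=config.operators,
            constant_range=config.constant_range,
        ),
        tree_spec=config.random_tree_spec,
        X_train=X_train,
        y_train=y_train,
        store=PedigreeStore(n_features=X_train.shape[1]),
        X_test=None if X_test is None else np.asarray(X_test, dtype=float),
        y_test=None if y_test is None else np.asarray(y_test, dtype=float),
    )
    pop = _init_population(config, ctx, rng)
    stats = [_population_stats(0, pop)]
    for t in range(1, config.generations + 1):
        pop, gen_stats = step_generation(pop, config, ctx, rng, t)
        stats.append(gen_stats)
    best = min(pop, key=_fitness_key)
    return RunTrace(config=config, stats=stats, best_id=best.id, store=ctx.store)


def run_evolution(config: RunConfig, train, test=None) -> RunTrace:
    """Run one evolution on :class:`~gsgp.data.Dataset` train/test splits."""
    if test is None:
        return run_evolution_arrays(config, train.X, train.y)
    return run_evolution_arrays(config, train.X, train.y, test.X, test.y)
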