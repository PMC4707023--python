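"""scikit-learn estimator front end for the GSGP engine.

:class:`GSGPRegressor` wraps one seeded evolutionary run behind the usual
``fit`` / ``predict`` contract, so the engine composes with sklearn
pipelines, cross-validation and model selection.  ``fit`` runs the
generational loop on the training data (optionally tracking a held-out
``eval_set`` per generation, as the study protocol does); ``predict``
evaluates the best evolved model through its lineage without ever
materialising the full expression tree.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .evolution import RunConfig, run_evolution_arrays
from .expressions import ExpressionNode, to_prefix
from .semantics import lineage_semantics, reconstruct_expression

__all__ = ["GSGPRegressor"]


class GSGPRegressor(RegressorMixin, BaseEstimator):
    """Symbolic regression by geometric semantic genetic programming.

    Parameters
    ----------
    population_size, generations:
        Scale of the evolutionary run.  Defaults (50, 200) are a desk-scale
        analogue of the full 1000-generation benchmark protocol.
    p_crossover, p_mutation, p_reproduction:
        Mutually exclusive per-offspring event probabilities; must sum to 1.
    mutation_step:
        The ball-mutation radius ``ms``; each output coordinate moves by at
        most this much per mutation.  Study values: 0.01, 0.1, 1.
    elitist:
        When True (the elitist system), a crossover child enters the
        population only if strictly fitter than both parents and a mutation
        child only if strictly fitter than its parent; otherwise a parent
        survives.  When False (standard GSGP) every child is kept, but the
        same success statistics are still recorded.
    surviving_parent_policy:
        Which crossover parent survives a rejected child: "best" or
        "random".
    best_survives:
        Copy the incumbent best unchanged into the next population.
    random_tree_max_depth:
        Depth budget ``D`` of the random trees consumed by the operators.
    random_state:
        Seed for the single RNG driving the whole run; same seed, data and
        parameters give a bit-identical run.

    Attributes
    ----------
    best_individual_ : the best-on-training individual of the final
        generation (semantics, exact size, lineage).
    best_size_ : exact node count of the best model (Python int).
    train_rmse_ : its training RMSE.
    trace_ : the full :class:`~gsgp.evolution.RunTrace`.
    store_ : the pedigree store backing lineage queries.
    """

    def __init__(
        self,
        population_size: int = 50,
        generations: int = 200,
        p_crossover: float = 0.7,
        p_mutation: float = 0.25,
        p_reproduction: float = 0.05,
        mutation_step: float = 1.0,
        tournament_size: int = 4,
        elitist: bool = True,
        surviving_parent_policy: str = "best",
        best_survives: bool = True,
        random_tree_max_depth: int = 6,
        random_tree_method: str = "grow",
        init_min_depth: int = 2,
        init_max_depth: int = 6,
        operators: tuple[str, ...] = ("add", "sub", "mul", "div"),
        constant_range: tuple[float, float] = (-1.0, 1.0),
        size_guard: int = 2**17,
        random_state: int | None = None,
    ):
        self.population_size = population_size
        self.generations = generations
        self.p_crossover = p_crossover
        self.p_mutation = p_mutation
        self.p_reproduction = p_reproduction
        self.mutation_step = mutation_step
        self.tournament_size = tournament_size
        self.elitist = elitist
        self.surviving_parent_policy = surviving_parent_policy
        self.best_survives = best_survives
        self.random_tree_max_depth = random_tree_max_depth
        self.random_tree_method = random_tree_method
        self.init_min_depth = init_min_depth
        self.init_max_depth = init_max_depth
        self.operators = operators
        self.constant_range = constant_range
        self.size_guard = size_guard
        self.random_state = random_state

    def _resolved_seed(self) -> int:
        if self.random_state is None:
            return int(np.random.SeedSequence().generate_state(1)[0] % 2**31)
        return int(self.random_state)

    def _config(self) -> RunConfig:
        return RunConfig(
            population_size=self.population_size,
            generations=self.generations,
            p_crossover=self.p_crossover,
            p_mutation=self.p_mutation,
            p_reproduction=self.p_reproduction,
            mutation_step=self.mutation_step,
            tournament_size=self.tournament_size,
            elitist_replacement=self.elitist,
            surviving_parent_policy=self.surviving_parent_policy,
            best_survives=self.best_survives,
            seed=self._resolved_seed(),
            random_tree_max_depth=self.random_tree_max_depth,
            random_tree_method=self.random_tree_method,
            init_min_depth=self.init_min_depth,
            init_max_depth=self.init_max_depth,
            operators=tuple(self.operators),
            constant_range=tuple(self.constant_range),
            size_guard=self.size_guard,
        )

    def fit(self, X, y, eval_set: tuple | None = None):
        """Run the seeded evolution; optionally track ``(X_test, y_test)``."""
        X, y = validate_data(self, X, y, y_numeric=True)
        X_test = y_test = None
        if eval_set is not None:
            X_test, y_test = eval_set
            X_test = np.asarray(X_test, dtype=float)
            y_test = np.asarray(y_test, dtype=float)
        trace = run_evolution_arrays(self._config(), X, y, X_test, y_test)
        self.trace_ = trace
        self.store_ = trace.store
        self.best_individual_ = trace.best
        self.best_size_ = trace.best.size
        self.train_rmse_ = trace.best.train_fitness
        return self

    def predict(self, X):
        """Evaluate the best model on new data through its lineage (O(g))."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return lineage_semantics(self.best_individual_, X, self.store_)

    def reconstruct(self, size_guard: int | None = None) -> ExpressionNode:
        """Unfold the best model into a full syntax tree.

        Refuses (raising :class:`~gsgp.semantics.ModelTooLargeError`, which
        carries the exact size) when the model exceeds the guard.
        """
        check_is_fitted(self)
        guard = self.size_guard if size_guard is None else size_guard
        return reconstruct_expression(self.best_individual_, self.store_, guard)

    def expression_text(self, size_guard: int | None = None) -> str:
        """The best model as a parenthesised prefix expression."""
        return to_prefix(self.reconstruct(size_guard))
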