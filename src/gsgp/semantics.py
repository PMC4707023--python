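"""The memory-efficient geometric semantic representation.

An individual is identified with its *semantics* — the vector of its outputs
on the training (and, when available, test) instances — plus an exact node
count and a lineage record saying how it was made.  The geometric semantic
operators act directly on semantics in O(n) per offspring:

* crossover:  ``child(i) = p1(i) * r(i) + (1 - r(i)) * p2(i)`` with a single
  random tree ``r`` whose outputs lie in [0, 1] (the tree appears twice in
  the offspring's genotype and is therefore counted twice in its size);
* mutation:   ``child(i) = t(i) + ms * (r1(i) - r2(i))`` with two distinct
  random [0, 1] trees and a mutation step ``ms`` bounding the per-coordinate
  perturbation.

Only generation-0 trees and the random trees are ever stored as syntax; the
full model can be reconstructed on demand by unfolding the lineage, and
unseen instances can be evaluated in time proportional to the number of
stored trees touched by the lineage, not to the (possibly astronomical)
unfolded node count.

Sizes are exact Python integers: final-model node counts can exceed 1e49,
far past 64-bit float integer precision, so no float ever touches them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expressions import (
    DEPTH17_NODE_BUDGET,
    ExpressionNode,
    constant,
    evaluate_tree,
    node_count,
    operator_node,
)
from .metrics import rmse

__all__ = [
    "LineageRecord",
    "StoredTree",
    "Individual",
    "PedigreeStore",
    "ModelTooLargeError",
    "make_genesis_individual",
    "reproduce",
    "semantic_crossover",
    "semantic_mutation",
    "size_of_offspring",
    "reconstruct_expression",
    "lineage_semantics",
    "evaluate_unseen",
]

_OP_KINDS = ("genesis", "crossover", "mutation", "reproduction")

# combiner-node constants of the two operators: crossover adds one +, two *,
# one -, and the literal 1 (5 nodes); mutation adds one +, one *, one -, and
# the ms constant (4 nodes)
CROSSOVER_EXTRA_NODES = 5
MUTATION_EXTRA_NODES = 4


class ModelTooLargeError(RuntimeError):
    """Raised when a model is too large to reconstruct as a syntax tree."""

    def __init__(self, size: int, guard: int):
        self.size = size
        self.guard = guard
        super().__init__(
            f"model unmanageable: exact size {size} nodes exceeds the "
            f"reconstruction guard of {guard} nodes"
        )


@dataclass(frozen=True)
class LineageRecord:
    """How an individual was made.

    genesis:      a generation-0 tree (``genesis_tree_id``), no parents.
    crossover:    two parents and ONE random tree, used twice.
    mutation:     one parent, two distinct random trees, and ``ms``.
    reproduction: one parent, nothing else.
    """

    op_kind: str
    parent_ids: tuple[int, ...] = ()
    random_tree_ids: tuple[int, ...] = ()
    ms: float | None = None
    genesis_tree_id: int | None = None

    def __post_init__(self) -> None:
        if self.op_kind not in _OP_KINDS:
            raise ValueError(f"unknown op_kind {self.op_kind!r}")
        shape = {
            "genesis": (0, 0),
            "crossover": (2, 1),
            "mutation": (1, 2),
            "reproduction": (1, 0),
        }[self.op_kind]
        if (len(self.parent_ids), len(self.random_tree_ids)) != shape:
            raise ValueError(
                f"{self.op_kind} lineage requires {shape[0]} parents and "
                f"{shape[1]} random trees"
            )
        if self.op_kind == "genesis" and self.genesis_tree_id is None:
            raise ValueError("genesis lineage requires a stored tree")
        if self.op_kind == "mutation" and (self.ms is None or self.ms <= 0):
            raise ValueError("mutation lineage requires a positive mutation step")


@dataclass(frozen=True)
class StoredTree:
    """A syntax tree kept in the pedigree pool, with cached semantics."""

    id: int
    tree: ExpressionNode
    size: int
    train_values: np.ndarray
    test_values: np.ndarray | None = None


@dataclass(frozen=True, eq=False)
class Individual:
    """Semantics, fitness, exact size and lineage of one program."""

    id: int
    train_semantics: np.ndarray
    train_fitness: float
    size: int
    lineage: LineageRecord
    test_semantics: np.ndarray | None = None
    test_fitness: float | None = None
    lineage_depth: int = 0


class PedigreeStore:
    """Append-only pool of stored trees and individual records.

    Entries are never mutated after insertion; every reference in any
    lineage record resolves within the same store.
    """

    def __init__(self, n_features: int | None = None):
        self.n_features = n_features
        self._trees: list[StoredTree] = []
        self._individuals: list[Individual] = []

    # -- trees --------------------------------------------------------
    def add_tree(
        self,
        tree: ExpressionNode,
        train_values: np.ndarray,
        test_values: np.ndarray | None = None,
    ) -> StoredTree:
        rec = StoredTree(
            id=len(self._trees),
            tree=tree,
            size=node_count(tree),
            train_values=np.asarray(train_values, dtype=float),
            test_values=None if test_values is None else np.asarray(test_values, float),
        )
        self._trees.append(rec)
        return rec

    def tree(self, tree_id: int) -> StoredTree:
        return self._trees[tree_id]

    # -- individuals --------------------------------------------------
    def add_individual(
        self,
        train_semantics: np.ndarray,
        train_fitness: float,
        size: int,
        lineage: LineageRecord,
        test_semantics: np.ndarray | None = None,
        test_fitness: float | None = None,
        lineage_depth: int = 0,
    ) -> Individual:
        if size < 1:
            raise ValueError("size must be >= 1")
        ind = Individual(
            id=len(self._individuals),
            train_semantics=np.asarray(train_semantics, dtype=float),
            train_fitness=float(train_fitness),
            size=int(size),
            lineage=lineage,
            test_semantics=(
                None if test_semantics is None else np.asarray(test_semantics, float)
            ),
            test_fitness=None if test_fitness is None else float(test_fitness),
            lineage_depth=lineage_depth,
        )
        self._individuals.append(ind)
        return ind

    def individual(self, ind_id: int) -> Individual:
        return self._individuals[ind_id]

    @property
    def n_trees(self) -> int:
        return len(self._trees)

    @property
    def n_individuals(self) -> int:
        return len(self._individuals)

    def lineage_json(self) -> dict:
        """A JSON-ready dump of the pedigree (ids, op kinds, refs, sizes)."""
        return {
            "trees": [{"id": t.id, "size": t.size} for t in self._trees],
            "individuals": [
                {
                    "id": i.id,
                    "op_kind": i.lineage.op_kind,
                    "parents": list(i.lineage.parent_ids),
                    "random_trees": list(i.lineage.random_tree_ids),
                    "ms": i.lineage.ms,
                    "genesis_tree": i.lineage.genesis_tree_id,
                    "size": i.size,
                }
                for i in self._individuals
            ],
        }


# ---------------------------------------------------------------------------
# constructors


def make_genesis_individual(
    tree: ExpressionNode,
    X_train: np.ndarray,
    y_train: np.ndarray,
    store: PedigreeStore,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
) -> Individual:
    """Create a generation-0 individual from a raw tree."""
    train_vals = evaluate_tree(tree, X_train)
    test_vals = None if X_test is None else evaluate_tree(tree, X_test)
    stored = store.add_tree(tree, train_vals, test_vals)
    lineage = LineageRecord(op_kind="genesis", genesis_tree_id=stored.id)
    return store.add_individual(
        train_semantics=train_vals,
        train_fitness=rmse(train_vals, y_train),
        size=stored.size,
        lineage=lineage,
        test_semantics=test_vals,
        test_fitness=None if y_test is None else rmse(test_vals, y_test),
        lineage_depth=0,
    )


def reproduce(parent: Individual, store: PedigreeStore) -> Individual:
    """Copy an individual into a new record with a reproduction lineage."""
    return store.add_individual(
        train_semantics=parent.train_semantics,
        train_fitness=parent.train_fitness,
        size=parent.size,
        lineage=LineageRecord(op_kind="reproduction", parent_ids=(parent.id,)),
        test_semantics=parent.test_semantics,
        test_fitness=parent.test_fitness,
        lineage_depth=parent.lineage_depth + 1,
    )


def _check_unit_interval(values: np.ndarray, label: str) -> None:
    if values is not None and (np.any(values < 0.0) or np.any(values > 1.0)):
        raise ValueError(f"{label}: random-tree semantics must lie in [0, 1]")


# ---------------------------------------------------------------------------
# the geometric semantic operators


def semantic_crossover(
    p1: Individual,
    p2: Individual,
    r: StoredTree,
    store: PedigreeStore,
    y_train: np.ndarray,
    y_test: np.ndarray | None = None,
) -> Individual:
    """Geometric semantic crossover: (T1 * TR) + ((1 - TR) * T2).

    Per coordinate the child is a convex combination of the parents with
    weight ``r(i)``, so it lies on the segment joining the parents in
    semantic space.  Its exact size is
    ``size(p1) + size(p2) + 2 * size(r) + 5``.
    """
    if p1.train_semantics.shape != p2.train_semantics.shape:
        raise ValueError("parents' training semantics lengths differ")
    if r.train_values.shape != p1.train_semantics.shape:
        raise ValueError("random-tree semantics length differs from the parents'")
    _check_unit_interval(r.train_values, "crossover (train)")
    _check_unit_interval(r.test_values, "crossover (test)")

    w = r.train_values
    child_train = p1.train_semantics * w + (1.0 - w) * p2.train_semantics
    child_test = None
    if p1.test_semantics is not None and p2.test_semantics is not None:
        wt = r.test_values
        child_test = p1.test_semantics * wt + (1.0 - wt) * p2.test_semantics

    lineage = LineageRecord(
        op_kind="crossover",
        parent_ids=(p1.id, p2.id),
        random_tree_ids=(r.id,),
    )
    return store.add_individual(
        train_semantics=child_train,
        train_fitness=rmse(child_train, y_train),
        size=size_of_offspring("crossover", (p1.size, p2.size), (r.size,)),
        lineage=lineage,
        test_semantics=child_test,
        test_fitness=None if y_test is None else rmse(child_test, y_test),
        lineage_depth=max(p1.lineage_depth, p2.lineage_depth) + 1,
    )


def semantic_mutation(
    t: Individual,
    r1: StoredTree,
    r2: StoredTree,
    ms: float,
    store: PedigreeStore,
    y_train: np.ndarray,
    y_test: np.ndarray | None = None,
) -> Individual:
    """Geometric semantic (ball) mutation: T + ms * (TR1 - TR2).

    Because both random trees map into [0, 1], every coordinate moves by at
    most ``ms``.  Exact size: ``size(t) + size(r1) + size(r2) + 4``.
    """
    if ms <= 0:
        raise ValueError("mutation step ms must be positive")
    if r1 is r2:
        raise ValueError("mutation requires two distinct random trees")
    _check_unit_interval(r1.train_values, "mutation (train)")
    _check_unit_interval(r2.train_values, "mutation (train)")

    child_train = t.train_semantics + ms * (r1.train_values - r2.train_values)
    child_test = None
    if t.test_semantics is not None:
        child_test = t.test_semantics + ms * (r1.test_values - r2.test_values)

    lineage = LineageRecord(
        op_kind="mutation",
        parent_ids=(t.id,),
        random_tree_ids=(r1.id, r2.id),
        ms=float(ms),
    )
    return store.add_individual(
        train_semantics=child_train,
        train_fitness=rmse(child_train, y_train),
        size=size_of_offspring("mutation", (t.size,), (r1.size, r2.size)),
        lineage=lineage,
        test_semantics=child_test,
        test_fitness=None if y_test is None else rmse(child_test, y_test),
        lineage_depth=t.lineage_depth + 1,
    )


def size_of_offspring(
    op_kind: str,
    parent_sizes: tuple[int, ...],
    random_tree_sizes: tuple[int, ...] = (),
) -> int:
    """Exact node count of an offspring from its parents' node counts.

    Crossover copies both parents and the random tree twice, glued by 5
    combiner nodes; mutation copies the parent and both random trees, glued
    by 4 nodes; reproduction copies the parent unchanged.  Pure integer
    arithmetic: no overflow at any generation count.
    """
    if any(s < 1 for s in parent_sizes) or any(s < 1 for s in random_tree_sizes):
        raise ValueError("sizes must be positive")
    if op_kind == "crossover":
        (s1, s2), (r,) = parent_sizes, random_tree_sizes
        return s1 + s2 + 2 * r + CROSSOVER_EXTRA_NODES
    if op_kind == "mutation":
        (s,), (r1, r2) = parent_sizes, random_tree_sizes
        return s + r1 + r2 + MUTATION_EXTRA_NODES
    if op_kind in ("reproduction", "genesis"):
        (s,) = parent_sizes
        return s
    raise ValueError(f"unknown op_kind {op_kind!r}")


# ---------------------------------------------------------------------------
# lineage unfolding


def _lineage_order(ind: Individual, store: PedigreeStore) -> list[Individual]:
    """Ancestors of ``ind`` (inclusive) in dependency (post) order."""
    order: list[Individual] = []
    seen: set[int] = set()
    stack: list[tuple[Individual, bool]] = [(ind, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            order.append(node)
            continue
        if node.id in seen:
            continue
        seen.add(node.id)
        stack.append((node, True))
        for pid in node.lineage.parent_ids:
            stack.append((store.individual(pid), False))
    return order


def reconstruct_expression(
    ind: Individual, store: PedigreeStore, size_guard: int = DEPTH17_NODE_BUDGET
) -> ExpressionNode:
    """Unfold an individual's lineage into a full syntax tree.

    Crossover expands to ``(T1 * TR) + ((1 - TR) * T2)`` with two
    references to the same stored random tree; mutation to
    ``T + ms * (TR1 - TR2)``.  The result's node count (counting shared
    subtrees with multiplicity) equals ``ind.size`` exactly.

    Raises :class:`ModelTooLargeError` when ``ind.size > size_guard`` —
    reconstruction of an unmanageable model is refused rather than
    attempted.
    """
    if ind.size > size_guard:
        raise ModelTooLargeError(ind.size, size_guard)
    built: dict[int, ExpressionNode] = {}
    for node in _lineage_order(ind, store):
        lr = node.lineage
        if lr.op_kind == "genesis":
            expr = store.tree(lr.genesis_tree_id).tree
        elif lr.op_kind == "reproduction":
            expr = built[lr.parent_ids[0]]
        elif lr.op_kind == "crossover":
            t1, t2 = (built[pid] for pid in lr.parent_ids)
            r = store.tree(lr.random_tree_ids[0]).tree
            expr = operator_node(
                "add",
                operator_node("mul", t1, r),
                operator_node("mul", operator_node("sub", constant(1.0), r), t2),
            )
        else:  # mutation
            t = built[lr.parent_ids[0]]
            r1, r2 = (store.tree(tid).tree for tid in lr.random_tree_ids)
            expr = operator_node(
                "add",
                t,
                operator_node(
                    "mul", constant(lr.ms), operator_node("sub", r1, r2)
                ),
            )
        built[node.id] = expr
    return built[ind.id]


def lineage_semantics(ind: Individual, X, store: PedigreeStore) -> np.ndarray:
    """Evaluate the model on new data without materialising the full tree.

    Each stored tree touched by the lineage is evaluated on ``X`` exactly
    once; outputs are then combined through the operator formulas up the
    lineage DAG.  Cost grows with the number of stored trees in the
    lineage (O(g) per instance), never with the unfolded model size.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if store.n_features is not None and X.shape[1] != store.n_features:
        raise ValueError(
            f"row width {X.shape[1]} does not match the store's "
            f"{store.n_features} features"
        )
    tree_vals: dict[int, np.ndarray] = {}

    def tval(tree_id: int) -> np.ndarray:
        if tree_id not in tree_vals:
            tree_vals[tree_id] = evaluate_tree(store.tree(tree_id).tree, X)
        return tree_vals[tree_id]

    out: dict[int, np.ndarray] = {}
    for node in _lineage_order(ind, store):
        lr = node.lineage
        if lr.op_kind == "genesis":
            v = tval(lr.genesis_tree_id)
        elif lr.op_kind == "reproduction":
            v = out[lr.parent_ids[0]]
        elif lr.op_kind == "crossover":
            w = tval(lr.random_tree_ids[0])
            v = out[lr.parent_ids[0]] * w + (1.0 - w) * out[lr.parent_ids[1]]
        else:
            v = out[lr.parent_ids[0]] + lr.ms * (
                tval(lr.random_tree_ids[0]) - tval(lr.random_tree_ids[1])
            )
        out[node.id] = v
    return out[ind.id]


def evaluate_unseen(ind: Individual, x, store: PedigreeStore) -> float:
    """The model's output on a single unseen input row."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be a single input row")
    return float(lineage_semantics(ind, x[None, :], store)[0])
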