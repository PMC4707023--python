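"""Syntax trees over binary arithmetic primitives.

This is the only module in which program *syntax* lives.  Everything the
evolutionary engine does at run time happens on semantics vectors; syntax
trees appear in three places only: the generation-0 population, the random
trees consumed by the geometric semantic operators, and models reconstructed
on demand from their lineage.

Trees are immutable.  The primitive set is restricted to binary arithmetic
operators (addition, subtraction, multiplication, protected division) so
that the closed-form size accounting used elsewhere — a depth-``D`` tree is
budgeted at ``2**D`` nodes under the convention adopted for the growth
bound — applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "PrimitiveSet",
    "ExpressionNode",
    "RandomTreeSpec",
    "variable",
    "constant",
    "operator_node",
    "squash",
    "generate_random_tree",
    "node_count",
    "depth",
    "max_variable_index",
    "evaluate_tree",
    "binary_tree_node_budget",
    "to_prefix",
    "from_prefix",
    "DEPTH17_NODE_BUDGET",
]

#: Koza's customary depth limit of 17 translated to a node budget with
#: binary primitives; the boundary between "manageable" and "unmanageable"
#: models.
DEPTH17_NODE_BUDGET = 2**17

_PROTECTED_EPS = 1e-6


def _protected_div(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Division that returns 1 wherever |denominator| <= 1e-6."""
    small = np.abs(b) <= _PROTECTED_EPS
    return np.where(small, 1.0, np.divide(a, np.where(small, 1.0, b)))


OPERATORS = {
    "add": np.add,
    "sub": np.subtract,
    "mul": np.multiply,
    "div": _protected_div,
}

_OP_SYMBOLS = {"add": "+", "sub": "-", "mul": "*", "div": "/"}
_SYMBOL_OPS = {v: k for k, v in _OP_SYMBOLS.items()}


class ExpressionError(ValueError):
    """Malformed expression tree or evaluation against incompatible data."""


@dataclass(frozen=True)
class PrimitiveSet:
    """The function and terminal sets available to tree generation.

    Parameters
    ----------
    n_features:
        Number of input variables ``x0 .. x{n_features-1}``.
    binary_ops:
        Names of the binary operators drawn from :data:`OPERATORS`.  All
        primitives have arity exactly two.
    constant_range:
        Closed interval from which ephemeral random constants are drawn.
    """

    n_features: int
    binary_ops: tuple[str, ...] = ("add", "sub", "mul", "div")
    constant_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ExpressionError("n_features must be >= 1")
        if not self.binary_ops:
            raise ExpressionError("at least one binary operator is required")
        unknown = set(self.binary_ops) - set(OPERATORS)
        if unknown:
            raise ExpressionError(f"unknown operators: {sorted(unknown)}")
        lo, hi = self.constant_range
        if not lo <= hi:
            raise ExpressionError("constant_range must be a nonempty interval")


@dataclass(frozen=True)
class ExpressionNode:
    """A node of an arithmetic expression tree.

    ``kind`` is one of ``"op"`` (binary operator, two children), ``"var"``
    (input variable leaf), ``"const"`` (numeric leaf) or ``"squash"``
    (the unary logistic wrapper that forces a random tree's codomain into
    [0, 1]; it counts as one node like every other symbol).
    """

    kind: str
    op: str | None = None
    children: tuple["ExpressionNode", ...] = ()
    index: int | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "op":
            if self.op not in OPERATORS:
                raise ExpressionError(f"unknown operator {self.op!r}")
            if len(self.children) != 2:
                raise ExpressionError("operator nodes take exactly two children")
        elif self.kind == "squash":
            if len(self.children) != 1:
                raise ExpressionError("squash takes exactly one child")
        elif self.kind == "var":
            if self.children or self.index is None or self.index < 0:
                raise ExpressionError("variable leaves need a nonnegative index")
        elif self.kind == "const":
            if self.children or self.value is None:
                raise ExpressionError("constant leaves need a value")
        else:
            raise ExpressionError(f"unknown node kind {self.kind!r}")


def variable(index: int) -> ExpressionNode:
    return ExpressionNode(kind="var", index=index)


def constant(value: float) -> ExpressionNode:
    return ExpressionNode(kind="const", value=float(value))


def operator_node(op: str, left: ExpressionNode, right: ExpressionNode) -> ExpressionNode:
    return ExpressionNode(kind="op", op=op, children=(left, right))


def squash(child: ExpressionNode) -> ExpressionNode:
    """Wrap a tree in the logistic function 1 / (1 + exp(-t))."""
    return ExpressionNode(kind="squash", children=(child,))


@dataclass(frozen=True)
class RandomTreeSpec:
    """How random trees are generated.

    ``max_depth`` is the depth bound ``D`` that enters the growth
    recurrence; ``method`` is Koza's grow or full initialisation;
    ``unit_interval_wrap`` composes the raw tree with the logistic squash
    so that every output lies in [0, 1], as the geometric semantic
    operators require of their random trees.
    """

    max_depth: int = 6
    method: str = "grow"
    unit_interval_wrap: bool = True

    def __post_init__(self) -> None:
        if self.max_depth < 0:
            raise ExpressionError("max_depth must be >= 0")
        if self.method not in ("grow", "full"):
            raise ExpressionError("method must be 'grow' or 'full'")


def _random_leaf(prims: PrimitiveSet, rng: np.random.Generator) -> ExpressionNode:
    # one ephemeral-constant slot competes with the variables
    if rng.random() < prims.n_features / (prims.n_features + 1):
        return variable(int(rng.integers(prims.n_features)))
    lo, hi = prims.constant_range
    return constant(float(rng.uniform(lo, hi)))


def _random_subtree(
    prims: PrimitiveSet, depth_left: int, method: str, rng: np.random.Generator
) -> ExpressionNode:
    n_ops = len(prims.binary_ops)
    pick_op = depth_left > 0 and (
        method == "full" or rng.random() < n_ops / (n_ops + prims.n_features + 1)
    )
    if not pick_op:
        return _random_leaf(prims, rng)
    op = prims.binary_ops[int(rng.integers(n_ops))]
    left = _random_subtree(prims, depth_left - 1, method, rng)
    right = _random_subtree(prims, depth_left - 1, method, rng)
    return operator_node(op, left, right)


def generate_random_tree(
    prims: PrimitiveSet, spec: RandomTreeSpec, rng: np.random.Generator
) -> ExpressionNode:
    """Generate a random tree of depth at most ``spec.max_depth``.

    When ``spec.unit_interval_wrap`` is set, the raw tree is composed with
    the logistic squash, so the returned tree's outputs always lie in
    [0, 1]; the wrapper counts as one node.
    """
    raw = _random_subtree(prims, spec.max_depth, spec.method, rng)
    return squash(raw) if spec.unit_interval_wrap else raw


def node_count(t: ExpressionNode) -> int:
    """Exact number of nodes; every symbol (operator, leaf, squash) is 1.

    Traversal is iterative and counts shared subtrees with multiplicity,
    so it agrees with the unfolded size of reconstructed lineages in which
    the same random-tree object appears twice.
    """
    total = 0
    stack = [t]
    while stack:
        node = stack.pop()
        total += 1
        stack.extend(node.children)
    return total


def depth(t: ExpressionNode) -> int:
    """Depth in edges: a single leaf has depth 0."""
    best = 0
    stack = [(t, 0)]
    while stack:
        node, d = stack.pop()
        if node.children:
            stack.extend((c, d + 1) for c in node.children)
        else:
            best = max(best, d)
    return best


def max_variable_index(t: ExpressionNode) -> int:
    """Largest variable index used, or -1 for a constant-only tree."""
    best = -1
    stack = [t]
    while stack:
        node = stack.pop()
        if node.kind == "var":
            best = max(best, node.index)
        stack.extend(node.children)
    return best


def evaluate_tree(t: ExpressionNode, X) -> np.ndarray:
    """Evaluate ``t`` pointwise on an (n_instances, n_features) matrix.

    Division is protected (returns 1 where |denominator| <= 1e-6), so the
    result is finite whenever the input is.  Evaluation uses an explicit
    stack; tree depth is not limited by Python's recursion limit.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ExpressionError("X must be a 2-D matrix of shape (n_instances, n_features)")
    n, width = X.shape
    values: list[np.ndarray] = []
    stack: list[tuple[ExpressionNode, bool]] = [(t, False)]
    while stack:
        node, expanded = stack.pop()
        if not expanded:
            stack.append((node, True))
            for child in reversed(node.children):
                stack.append((child, False))
            continue
        if node.kind == "var":
            if node.index >= width:
                raise ExpressionError(
                    f"variable x{node.index} out of range for {width} features"
                )
            values.append(X[:, node.index])
        elif node.kind == "const":
            values.append(np.full(n, node.value))
        elif node.kind == "squash":
            values.append(expit(values.pop()))
        else:
            right = values.pop()
            left = values.pop()
            values.append(OPERATORS[node.op](left, right))
    return np.asarray(values[-1], dtype=float)


def binary_tree_node_budget(D: int) -> int:
    """Node budget 2**D of a depth-``D`` tree under the binary-primitive
    counting convention used by the growth recurrence.

    This deliberately undercounts a true full binary tree, which has
    ``2**(D+1) - 1`` nodes; the growth-analysis module exposes both
    conventions.
    """
    if D < 0:
        raise ExpressionError("depth must be >= 0")
    return 1 << D


# ---------------------------------------------------------------------------
# prefix (s-expression) serialisation


def to_prefix(t: ExpressionNode) -> str:
    """Render a tree as a parenthesised prefix expression.

    Constants are printed with ``repr`` so the round trip through
    :func:`from_prefix` is exact.
    """
    if t.kind == "var":
        return f"x{t.index}"
    if t.kind == "const":
        return repr(t.value)
    if t.kind == "squash":
        return f"(squash {to_prefix(t.children[0])})"
    left, right = t.children
    return f"({_OP_SYMBOLS[t.op]} {to_prefix(left)} {to_prefix(right)})"


def _tokenize(text: str) -> list[str]:
    return text.replace("(", " ( ").replace(")", " ) ").split()


def from_prefix(text: str) -> ExpressionNode:
    """Parse the output of :func:`to_prefix` back into a tree."""
    tokens = _tokenize(text)
    pos = 0

    def parse() -> ExpressionNode:
        nonlocal pos
        if pos >= len(tokens):
            raise ExpressionError("unexpected end of expression")
        tok = tokens[pos]
        pos += 1
        if tok == "(":
            head = tokens[pos]
            pos += 1
            if head == "squash":
                child = parse()
                node = squash(child)
            elif head in _SYMBOL_OPS:
                left = parse()
                right = parse()
                node = operator_node(_SYMBOL_OPS[head], left, right)
            else:
                raise ExpressionError(f"unknown head symbol {head!r}")
            if pos >= len(tokens) or tokens[pos] != ")":
                raise ExpressionError("missing closing parenthesis")
            pos += 1
            return node
        if tok == ")":
            raise ExpressionError("unexpected ')'")
        if tok.startswith("x") and tok[1:].isdigit():
            return variable(int(tok[1:]))
        try:
            return constant(float(tok))
        except ValueError as exc:
            raise ExpressionError(f"cannot parse token {tok!r}") from exc

    node = parse()
    if pos != len(tokens):
        raise ExpressionError("trailing tokens after expression")
    return node
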