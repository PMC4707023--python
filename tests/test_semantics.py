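"""Semantics-plus-lineage representation and the geometric operators."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gsgp.expressions import (
    PrimitiveSet,
    RandomTreeSpec,
    constant,
    evaluate_tree,
    generate_random_tree,
    node_count,
    operator_node,
    variable,
)
from gsgp.metrics import rmse
from gsgp.semantics import (
    LineageRecord,
    ModelTooLargeError,
    PedigreeStore,
    evaluate_unseen,
    lineage_semantics,
    make_genesis_individual,
    reconstruct_expression,
    semantic_crossover,
    semantic_mutation,
    size_of_offspring,
)

PRIMS = PrimitiveSet(n_features=3)


def fabricated(store, train, y, size=1, test=None, y_test=None):
    """Register an individual with hand-chosen semantics (genesis lineage
    over a dummy leaf), for operator-level tests."""
    train = np.asarray(train, dtype=float)
    stored = store.add_tree(variable(0), train, test)
    return store.add_individual(
        train_semantics=train,
        train_fitness=rmse(train, y),
        size=size,
        lineage=LineageRecord(op_kind="genesis", genesis_tree_id=stored.id),
        test_semantics=test,
        test_fitness=None if y_test is None else rmse(test, y_test),
    )


def fabricated_tree(store, values, test=None):
    return store.add_tree(variable(0), np.asarray(values, float), test)


class TestCrossover:
    def test_midpoint(self):
        store = PedigreeStore()
        y = np.array([0.0])
        p1 = fabricated(store, [1.0], y)
        p2 = fabricated(store, [3.0], y)
        r = fabricated_tree(store, [0.5])
        child = semantic_crossover(p1, p2, r, store, y)
        np.testing.assert_array_equal(child.train_semantics, [2.0])
        assert child.train_fitness == pytest.approx(2.0)

    def test_all_ones_weight_returns_first_parent(self):
        store = PedigreeStore()
        y = np.zeros(4)
        p1 = fabricated(store, [1.0, -2.0, 0.5, 4.0], y)
        p2 = fabricated(store, [9.0, 9.0, 9.0, 9.0], y)
        r = fabricated_tree(store, np.ones(4))
        child = semantic_crossover(p1, p2, r, store, y)
        np.testing.assert_array_equal(child.train_semantics, p1.train_semantics)

    def test_size_rule(self):
        store = PedigreeStore()
        y = np.zeros(2)
        p1 = fabricated(store, [1.0, 1.0], y, size=3)
        p2 = fabricated(store, [2.0, 2.0], y, size=3)
        r = fabricated_tree(store, [0.5, 0.5])  # size 1
        child = semantic_crossover(p1, p2, r, store, y)
        assert child.size == 3 + 3 + 2 * 1 + 5 == 13

    def test_weight_outside_unit_interval_rejected(self):
        store = PedigreeStore()
        y = np.zeros(1)
        p1 = fabricated(store, [1.0], y)
        p2 = fabricated(store, [2.0], y)
        r = fabricated_tree(store, [1.5])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            semantic_crossover(p1, p2, r, store, y)

    def test_mismatched_lengths_rejected(self):
        store = PedigreeStore()
        p1 = fabricated(store, [1.0, 2.0], np.zeros(2))
        p2 = fabricated(store, [1.0], np.zeros(1))
        r = fabricated_tree(store, [0.5, 0.5])
        with pytest.raises(ValueError, match="length"):
            semantic_crossover(p1, p2, r, store, np.zeros(2))

    @given(
        st.lists(
            st.tuples(
                st.floats(-1e6, 1e6), st.floats(-1e6, 1e6), st.floats(0.0, 1.0)
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_coordinate_convexity(self, triples):
        a, b, w = (np.array(v) for v in zip(*triples))
        store = PedigreeStore()
        y = np.zeros(a.size)
        child = semantic_crossover(
            fabricated(store, a, y), fabricated(store, b, y),
            fabricated_tree(store, w), store, y,
        )
        c = child.train_semantics
        assert np.all(c >= np.minimum(a, b) - 1e-9)
        assert np.all(c <= np.maximum(a, b) + 1e-9)


class TestMutation:
    def test_direct_arithmetic(self):
        store = PedigreeStore()
        y = np.zeros(2)
        t = fabricated(store, [1.0, 2.0], y)
        r1 = fabricated_tree(store, [1.0, 0.0])
        r2 = fabricated_tree(store, [0.0, 1.0])
        child = semantic_mutation(t, r1, r2, 0.5, store, y)
        np.testing.assert_array_equal(child.train_semantics, [1.5, 1.5])

    def test_tiny_step_barely_moves(self):
        store = PedigreeStore()
        y = np.zeros(3)
        t = fabricated(store, [1.0, -1.0, 0.0], y)
        r1 = fabricated_tree(store, [1.0, 1.0, 1.0])
        r2 = fabricated_tree(store, [0.0, 0.0, 0.0])
        child = semantic_mutation(t, r1, r2, 1e-12, store, y)
        np.testing.assert_allclose(child.train_semantics, t.train_semantics, atol=1e-11)

    def test_size_rule(self):
        store = PedigreeStore()
        y = np.zeros(1)
        t = fabricated(store, [0.0], y, size=1)
        r1 = fabricated_tree(store, [0.2])
        r2 = fabricated_tree(store, [0.8])
        child = semantic_mutation(t, r1, r2, 0.1, store, y)
        assert child.size == 1 + 1 + 1 + 4 == 7

    def test_nonpositive_step_rejected(self):
        store = PedigreeStore()
        y = np.zeros(1)
        t = fabricated(store, [0.0], y)
        r1 = fabricated_tree(store, [0.1])
        r2 = fabricated_tree(store, [0.9])
        with pytest.raises(ValueError, match="positive"):
            semantic_mutation(t, r1, r2, 0.0, store, y)

    def test_same_tree_twice_rejected(self):
        store = PedigreeStore()
        y = np.zeros(1)
        t = fabricated(store, [0.0], y)
        r = fabricated_tree(store, [0.5])
        with pytest.raises(ValueError, match="distinct"):
            semantic_mutation(t, r, r, 0.5, store, y)

    @given(
        st.lists(
            st.tuples(
                st.floats(-1e6, 1e6), st.floats(0.0, 1.0), st.floats(0.0, 1.0)
            ),
            min_size=1,
            max_size=40,
        ),
        st.floats(1e-3, 10.0),
    )
    def test_bounded_perturbation(self, triples, ms):
        base, w1, w2 = (np.array(v) for v in zip(*triples))
        store = PedigreeStore()
        y = np.zeros(base.size)
        child = semantic_mutation(
            fabricated(store, base, y),
            fabricated_tree(store, w1), fabricated_tree(store, w2),
            ms, store, y,
        )
        assert np.max(np.abs(child.train_semantics - base)) <= ms * (1 + 1e-12)


class TestSizeOfOffspring:
    @pytest.mark.parametrize(
        "op, parents, trees, expected",
        [
            ("reproduction", (42,), (), 42),
            ("crossover", (1, 1), (1,), 9),
            ("crossover", (3, 3), (1,), 13),
            ("mutation", (1,), (1, 1), 7),
        ],
    )
    def test_rules(self, op, parents, trees, expected):
        assert size_of_offspring(op, parents, trees) == expected

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="op_kind"):
            size_of_offspring("frobnicate", (1,), ())

    def test_exact_big_integer_arithmetic(self):
        s = 3
        for _ in range(200):  # self-crossover: s -> 2s + 2 + 5, stays exact
            s = size_of_offspring("crossover", (s, s), (1,))
        assert s == (3 + 7) * 2**200 - 7  # closed form of the recurrence


def run_lineage(ops, rng, n=12):
    """Build a small lineage by applying a scripted op sequence; returns
    (final individual, store, X, y)."""
    X = rng.uniform(-1, 1, size=(n, 3))
    y = rng.normal(size=n)
    store = PedigreeStore(n_features=3)
    spec = RandomTreeSpec(max_depth=2, method="grow")
    init = RandomTreeSpec(max_depth=3, method="grow", unit_interval_wrap=False)

    def fresh():
        t = generate_random_tree(PRIMS, spec, rng)
        return store.add_tree(t, evaluate_tree(t, X))

    cur = make_genesis_individual(generate_random_tree(PRIMS, init, rng), X, y, store)
    other = make_genesis_individual(generate_random_tree(PRIMS, init, rng), X, y, store)
    for op in ops:
        if op == "x":
            cur = semantic_crossover(cur, other, fresh(), store, y)
        elif op == "s":  # self-crossover: size roughly doubles
            cur = semantic_crossover(cur, cur, fresh(), store, y)
        else:
            cur = semantic_mutation(cur, fresh(), fresh(), 0.3, store, y)
    return cur, store, X, y


class TestReconstruction:
    def test_genesis_returns_stored_tree(self, rng):
        cur, store, X, y = run_lineage([], rng)
        assert reconstruct_expression(cur, store) is store.tree(
            cur.lineage.genesis_tree_id
        ).tree

    @pytest.mark.parametrize(
        "ops", ["x", "m", "xm", "mx", "xxx", "mmm", "xmxmxm", "mxxmxx"]
    )
    def test_node_count_equals_lineage_size(self, rng, ops):
        cur, store, _, _ = run_lineage(list(ops), rng)
        assert node_count(reconstruct_expression(cur, store)) == cur.size

    @pytest.mark.parametrize("ops", ["x", "xm", "xmxmxm"])
    def test_semantics_match_reevaluation(self, rng, ops):
        cur, store, X, _ = run_lineage(list(ops), rng)
        expr = reconstruct_expression(cur, store)
        np.testing.assert_allclose(
            evaluate_tree(expr, X), cur.train_semantics, rtol=1e-9
        )

    def test_guard_refuses_with_exact_size(self):
        store = PedigreeStore()
        ind = fabricated(store, [0.0], np.zeros(1), size=2**20)
        with pytest.raises(ModelTooLargeError, match=str(2**20)):
            reconstruct_expression(ind, store, size_guard=2**17)

    def test_parents_untouched_by_operators(self, rng):
        store = PedigreeStore()
        y = np.zeros(3)
        a = np.array([1.0, 2.0, 3.0])
        p1 = fabricated(store, a.copy(), y, size=5)
        p2 = fabricated(store, [0.0, 0.0, 0.0], y, size=5)
        before = (p1.train_semantics.copy(), p1.train_fitness, p1.size)
        semantic_crossover(p1, p2, fabricated_tree(store, [0.5, 0.5, 0.5]), store, y)
        semantic_mutation(
            p1, fabricated_tree(store, [1, 1, 1]), fabricated_tree(store, [0, 0, 0]),
            0.5, store, y,
        )
        np.testing.assert_array_equal(p1.train_semantics, before[0])
        assert (p1.train_fitness, p1.size) == before[1:]


class TestUnseenEvaluation:
    def test_genesis_equals_direct_evaluation(self, rng):
        cur, store, X, _ = run_lineage([], rng)
        tree = store.tree(cur.lineage.genesis_tree_id).tree
        x = rng.uniform(-1, 1, size=3)
        assert evaluate_unseen(cur, x, store) == pytest.approx(
            float(evaluate_tree(tree, x[None, :])[0])
        )

    @pytest.mark.parametrize("ops", ["x", "m", "xmxmxm"])
    def test_matches_reconstruction(self, rng, ops):
        cur, store, _, _ = run_lineage(list(ops), rng)
        expr = reconstruct_expression(cur, store)
        x = rng.uniform(-1, 1, size=3)
        expected = float(evaluate_tree(expr, x[None, :])[0])
        assert evaluate_unseen(cur, x, store) == pytest.approx(expected, rel=1e-9)

    def test_deep_lineage_without_reconstruction(self, rng):
        # 200 operator applications: the unfolded model is astronomically
        # large, yet lineage evaluation stays cheap and finite
        cur, store, _, _ = run_lineage(["s", "m"] * 100, rng)
        assert cur.size > 2**17
        val = evaluate_unseen(cur, np.array([0.1, -0.2, 0.3]), store)
        assert np.isfinite(val)

    def test_row_width_mismatch(self, rng):
        cur, store, _, _ = run_lineage(["x"], rng)
        with pytest.raises(ValueError, match="width"):
            evaluate_unseen(cur, np.zeros(5), store)


class TestPedigreeStore:
    def test_lineage_json_resolves(self, rng):
        cur, store, _, _ = run_lineage(["x", "m"], rng)
        dump = store.lineage_json()
        tree_ids = {t["id"] for t in dump["trees"]}
        ind_ids = {i["id"] for i in dump["individuals"]}
        for rec in dump["individuals"]:
            assert set(rec["parents"]) <= ind_ids
            assert set(rec["random_trees"]) <= tree_ids
            assert rec["size"] >= 1

    def test_lineage_record_shape_validation(self):
        with pytest.raises(ValueError):
            LineageRecord(op_kind="crossover", parent_ids=(1,), random_tree_ids=(2,))
        with pytest.raises(ValueError):
            LineageRecord(op_kind="mutation", parent_ids=(1,), random_tree_ids=(2, 3))
        with pytest.raises(ValueError):
            LineageRecord(op_kind="genesis")
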