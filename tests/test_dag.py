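"""d-separation, backdoor paths and adjustment sets vs brute-force oracles.

The oracles here are deliberately independent of the package's route:
d-separation is re-derived by enumerating undirected simple paths and
applying chain/fork/collider rules by hand, and adjustment-set validity is
re-derived by graph surgery (delete the exposure's outgoing edges, test
separation) over every subset of candidate nodes.
"""

from itertools import combinations

import numpy as np
import pytest

from panthoot.dag import (
    AdjustmentQuery,
    CausalDAG,
    backdoor_paths,
    d_separated,
    minimal_adjustment_sets,
    pant_hoot_dialect_dag,
    satisfies_backdoor,
)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def _descendants(edges, node):
    out = set()
    frontier = [node]
    while frontier:
        n = frontier.pop()
        for a, b in edges:
            if a == n and b not in out:
                out.add(b)
                frontier.append(b)
    return out


def _simple_paths(nodes, edges, x, y):
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    paths, stack = [], [[x]]
    while stack:
        p = stack.pop()
        if p[-1] == y:
            paths.append(p)
            continue
        for nxt in adj[p[-1]]:
            if nxt not in p:
                stack.append(p + [nxt])
    return paths


def _blocked(edges, path, Z):
    for i in range(1, len(path) - 1):
        into = (path[i - 1], path[i]) in edges
        out = (path[i], path[i + 1]) in edges
        if into and not out:  # collider
            if not ({path[i]} | _descendants(edges, path[i])) & Z:
                return True
        elif path[i] in Z:
            return True
    return False


def oracle_d_separated(dag, x, y, Z):
    Z = set(Z)
    return all(
        _blocked(dag.edges, p, Z) for p in _simple_paths(dag.nodes, dag.edges, x, y)
    )


def oracle_minimal_sets(dag, exposure, outcome):
    desc = _descendants(dag.edges, exposure)
    surgery_edges = frozenset(e for e in dag.edges if e[0] != exposure)
    surgery = CausalDAG(dag.nodes, surgery_edges, dag.observable)
    candidates = sorted(dag.observable - {exposure, outcome} - desc)
    valid = [
        frozenset(s)
        for r in range(len(candidates) + 1)
        for s in combinations(candidates, r)
        if oracle_d_separated(surgery, exposure, outcome, set(s))
    ]
    return {s for s in valid if not any(v < s for v in valid)}


def random_dag(rng, n_nodes):
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = frozenset(
        (nodes[i], nodes[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < 0.4
    )
    return CausalDAG(frozenset(nodes), edges)


# ---------------------------------------------------------------------------
# elementary structures
# ---------------------------------------------------------------------------


class TestElementaryStructures:
    def test_chain_blocked_by_middle(self):
        dag = CausalDAG.from_edge_list("a -> b\nb -> c")
        assert d_separated(dag, "a", "c", {"b"})
        assert not d_separated(dag, "a", "c", set())

    def test_collider_rule(self):
        dag = CausalDAG.from_edge_list("a -> b\nc -> b")
        assert d_separated(dag, "a", "c", set())
        assert not d_separated(dag, "a", "c", {"b"})

    def test_collider_descendant_opens(self):
        dag = CausalDAG.from_edge_list("a -> b\nc -> b\nb -> d")
        assert not d_separated(dag, "a", "c", {"d"})

    def test_fork(self):
        dag = CausalDAG.from_edge_list("b -> a\nb -> c")
        assert not d_separated(dag, "a", "c", set())
        assert d_separated(dag, "a", "c", {"b"})

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            CausalDAG.from_edge_list("a -> b\nb -> a")

    def test_unknown_node_rejected(self):
        dag = CausalDAG.from_edge_list("a -> b")
        with pytest.raises(ValueError):
            d_separated(dag, "a", "zzz", set())


class TestBackdoorPaths:
    def test_exposure_without_parents_has_none(self):
        dag = CausalDAG.from_edge_list("x -> y\nx -> m\nm -> y")
        assert backdoor_paths(dag, AdjustmentQuery("x", "y")) == []

    def test_classic_confounder_path(self):
        dag = CausalDAG.from_edge_list("u -> x\nu -> y\nx -> y")
        paths = backdoor_paths(dag, AdjustmentQuery("x", "y"))
        assert paths == [["x", "u", "y"]]

    def test_dialect_dag_contains_individual_path(self):
        dag = pant_hoot_dialect_dag()
        paths = backdoor_paths(dag, AdjustmentQuery("community", "acoustic_structure"))
        assert ["community", "individual", "acoustic_structure"] in paths

    def test_matches_exhaustive_enumeration_on_random_dags(self, rng):
        for _ in range(20):
            dag = random_dag(rng, 5)
            x, y = "n0", "n4"
            expected = sorted(
                (p for p in _simple_paths(dag.nodes, dag.edges, x, y)
                 if (p[1], p[0]) in dag.edges),
                key=lambda p: (len(p), p),
            )
            assert backdoor_paths(dag, AdjustmentQuery(x, y)) == expected


class TestAdjustmentSets:
    def test_dialect_dag_reproduces_both_published_sets(self):
        dag = pant_hoot_dialect_dag()
        sets = minimal_adjustment_sets(
            dag, AdjustmentQuery("community", "acoustic_structure")
        )
        assert sets == {
            frozenset({"individual", "location"}),
            frozenset({"environment", "genetics", "individual"}),
        }

    def test_no_backdoor_path_gives_empty_set(self):
        dag = CausalDAG.from_edge_list("x -> y\nx -> m\nm -> y")
        assert minimal_adjustment_sets(dag, AdjustmentQuery("x", "y")) == {frozenset()}

    def test_unobservable_confounder_gives_no_valid_set(self):
        dag = CausalDAG(
            frozenset({"u", "x", "y"}),
            frozenset({("u", "x"), ("u", "y"), ("x", "y")}),
            observable=frozenset({"x", "y"}),
        )
        assert minimal_adjustment_sets(dag, AdjustmentQuery("x", "y")) == set()

    def test_returned_sets_block_in_surgery_graph(self):
        dag = pant_hoot_dialect_dag()
        q = AdjustmentQuery("community", "acoustic_structure")
        surgery = CausalDAG(
            dag.nodes,
            frozenset(e for e in dag.edges if e[0] != q.exposure),
            dag.observable,
        )
        for s in minimal_adjustment_sets(dag, q):
            assert d_separated(surgery, q.exposure, q.outcome, s)

    def test_minimality_removing_any_node_breaks_criterion(self):
        dag = pant_hoot_dialect_dag()
        q = AdjustmentQuery("community", "acoustic_structure")
        for s in minimal_adjustment_sets(dag, q):
            for node in s:
                assert not satisfies_backdoor(dag, q, s - {node})

    def test_agrees_with_brute_force_on_random_dags(self, rng):
        checked = 0
        for n_nodes in (4, 5, 6, 7):
            for _ in range(10):
                dag = random_dag(rng, n_nodes)
                q = AdjustmentQuery("n0", f"n{n_nodes - 1}")
                assert minimal_adjustment_sets(dag, q) == oracle_minimal_sets(
                    dag, q.exposure, q.outcome
                )
                checked += 1
        assert checked == 40

    def test_d_separation_agrees_with_path_oracle_on_random_dags(self, rng):
        for _ in range(30):
            dag = random_dag(rng, 6)
            nodes = sorted(dag.nodes)
            x, y = nodes[0], nodes[-1]
            others = [n for n in nodes if n not in (x, y)]
            k = int(rng.integers(0, len(others) + 1))
            Z = set(rng.choice(others, size=k, replace=False)) if k else set()
            assert d_separated(dag, x, y, Z) == oracle_d_separated(dag, x, y, Z)
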