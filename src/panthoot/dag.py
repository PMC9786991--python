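"""Causal DAGs, backdoor paths, and minimally sufficient adjustment sets.

A community-dialect question ("does community identity cause acoustic
structure?") is confounded whenever a variable opens a backdoor path between
exposure and outcome — e.g. individual identity affects both which community
a male belongs to and how his calls sound.  This module represents the
assumed causal graph, answers d-separation queries, enumerates backdoor
paths, and returns every minimally sufficient adjustment set under the
backdoor criterion.

Graphs in this problem are tiny (<= 10 nodes), so adjustment-set search is an
exhaustive scan over subsets of the observable nodes — simple and provably
correct at this scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import yaml


@dataclass
class CausalDAG:
    """Directed acyclic graph over named nodes with an observability flag.

    ``observable`` is the subset of nodes eligible for statistical adjustment
    (latent constructs such as "genetics" may still appear in the graph but
    be excluded from adjustment if unmeasured; by default every node is
    observable).
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    observable: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.nodes = frozenset(self.nodes)
        self.edges = frozenset((str(a), str(b)) for a, b in self.edges)
        dangling = {n for e in self.edges for n in e} - self.nodes
        if dangling:
            raise ValueError(f"edges reference undeclared node(s): {sorted(dangling)}")
        if self.observable is None:
            self.observable = self.nodes
        self.observable = frozenset(self.observable) & self.nodes
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("graph contains a directed cycle")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> set[str]:
        return {a for a, b in self.edges if b == node}

    def descendants(self, node: str) -> set[str]:
        return set(nx.descendants(self.graph(), node))

    @classmethod
    def from_edge_list(cls, text: str, observable: Iterable[str] | None = None) -> "CausalDAG":
        """Parse a ``parent -> child`` per-line edge-list format."""
        edges = []
        nodes: set[str] = set()
        for line in text.splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "->" not in line:
                raise ValueError(f"cannot parse edge line: {line!r}")
            a, b = (part.strip() for part in line.split("->", 1))
            edges.append((a, b))
            nodes.update((a, b))
        return cls(frozenset(nodes), frozenset(edges),
                   frozenset(observable) if observable is not None else None)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CausalDAG":
        spec = yaml.safe_load(Path(path).read_text())
        edges = [tuple(e) if isinstance(e, (list, tuple)) else tuple(
            p.strip() for p in e.split("->")) for e in spec["edges"]]
        nodes = set(spec.get("nodes", [])) | {n for e in edges for n in e}
        obs = spec.get("observable")
        return cls(frozenset(nodes), frozenset(edges),
                   frozenset(obs) if obs is not None else None)


@dataclass(frozen=True)
class AdjustmentQuery:
    """An exposure -> outcome causal query on a :class:`CausalDAG`."""

    exposure: str
    outcome: str

    def validate(self, dag: CausalDAG) -> None:
        for node in (self.exposure, self.outcome):
            if node not in dag.nodes:
                raise ValueError(f"unknown node {node!r}")
        if self.exposure == self.outcome:
            raise ValueError("exposure and outcome must differ")


def d_separated(dag: CausalDAG, x: str, y: str, Z: Iterable[str] = ()) -> bool:
    """True iff every path between ``x`` and ``y`` is blocked given ``Z``.

    Standard chain/fork/collider semantics: a collider is open iff it or one
    of its descendants is in ``Z``.
    """
    Z = set(Z)
    unknown = ({x, y} | Z) - dag.nodes
    if unknown:
        raise ValueError(f"unknown node(s): {sorted(unknown)}")
    if x in Z or y in Z:
        raise ValueError("x and y must not be members of Z")
    return nx.is_d_separator(dag.graph(), {x}, {y}, Z)


def _undirected_paths(dag: CausalDAG, start: str, end: str) -> list[list[str]]:
    """All simple paths between start and end ignoring edge direction."""
    ug = dag.graph().to_undirected()
    return [list(p) for p in nx.all_simple_paths(ug, start, end)]


def backdoor_paths(dag: CausalDAG, q: AdjustmentQuery) -> list[list[str]]:
    """All undirected paths exposure -> outcome entering the exposure.

    A backdoor path starts with an edge *into* the exposure; such paths carry
    confounding rather than causal influence.
    """
    q.validate(dag)
    paths = []
    for p in _undirected_paths(dag, q.exposure, q.outcome):
        if (p[1], p[0]) in dag.edges:  # first hop points into the exposure
            paths.append(p)
    return sorted(paths, key=lambda p: (len(p), p))


def _path_blocked(dag: CausalDAG, path: Sequence[str], Z: set[str]) -> bool:
    """Chain/fork/collider blocking test for one undirected path."""
    for i in range(1, len(path) - 1):
        prev_into = (path[i - 1], path[i]) in dag.edges
        next_out = (path[i], path[i + 1]) in dag.edges
        if prev_into and not next_out:
            # collider: x -> m <- y; blocked unless m or a descendant is in Z
            if not ({path[i]} | dag.descendants(path[i])) & Z:
                return True
        else:
            # chain or fork: blocked iff the middle node is conditioned on
            if path[i] in Z:
                return True
    return False


def satisfies_backdoor(dag: CausalDAG, q: AdjustmentQuery, Z: Iterable[str]) -> bool:
    """Backdoor criterion: Z contains no descendant of the exposure and
    blocks every backdoor path from exposure to outcome."""
    q.validate(dag)
    Z = set(Z)
    if Z & (dag.descendants(q.exposure) | {q.exposure, q.outcome}):
        return False
    return all(_path_blocked(dag, p, Z) for p in backdoor_paths(dag, q))


def minimal_adjustment_sets(dag: CausalDAG, q: AdjustmentQuery) -> set[frozenset[str]]:
    """All minimally sufficient adjustment sets over the observable nodes.

    A returned set satisfies the backdoor criterion and no proper subset of
    it does.  If no backdoor path exists the unique answer is the empty set
    ``{frozenset()}``; if no observable subset works, the result is empty.
    """
    q.validate(dag)
    candidates = sorted(
        dag.observable - {q.exposure, q.outcome} - dag.descendants(q.exposure)
    )
    valid: list[frozenset[str]] = []
    for r in range(len(candidates) + 1):
        for combo in combinations(candidates, r):
            s = frozenset(combo)
            if any(v <= s for v in valid):
                continue  # supersets of a valid set are never minimal
            if satisfies_backdoor(dag, q, s):
                valid.append(s)
    return set(valid)


def pant_hoot_dialect_dag() -> CausalDAG:
    """The assumed causal graph for the community-dialect question.

    Geographical location shapes the acoustic environment, community
    membership, and genetics; genetics shapes individual identity and call
    structure; individual identity affects both call structure and community
    membership; context is a root with a single edge into acoustic structure.
    Querying community -> acoustic structure on this graph yields exactly two
    minimally sufficient adjustment sets: {individual, location} and
    {environment, genetics, individual}.
    """
    edges = [
        ("location", "environment"),
        ("location", "community"),
        ("location", "genetics"),
        ("genetics", "individual"),
        ("genetics", "acoustic_structure"),
        ("environment", "acoustic_structure"),
        ("individual", "acoustic_structure"),
        ("individual", "community"),
        ("context", "acoustic_structure"),
    ]
    nodes = {n for e in edges for n in e}
    return CausalDAG(frozenset(nodes), frozenset(edges))
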