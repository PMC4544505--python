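"""The line graph transformation, its iteration, limit class and line index.

The line graph L(G) has one vertex per edge of G, two vertices being
adjacent exactly when the parent edges share an endpoint.  Equivalently,
A(L(G)) = Z^T Z - 2 I computed from the incidence matrix of G; both routes
are implemented and compared in the test suite.

Iterating L captures the hierarchy of bonded interactions: vertices of
L^{n-1}(G) are the n-body terms of the molecule G.  As n grows a connected
graph has exactly four possible fates: cycles reproduce themselves, the
claw K_{1,3} collapses to a triangle, paths shrink to the null graph, and
every other ("prolific") graph grows without bound.  For prolific graphs
the line index xi(G) — the least m with L^m(G) nonplanar — satisfies
0 <= xi <= 4; non-prolific graphs stay planar forever.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import GraphValidationError, InternalConsistencyError
from .graph_core import MolecularGraph, matrices

__all__ = [
    "LineGraphLevel",
    "IterationResult",
    "LimitClass",
    "LineIndexResult",
    "edge_label",
    "line_graph",
    "adjacency_from_incidence",
    "iterate",
    "classify_limit",
    "line_index",
    "DEFAULT_VERTEX_BUDGET",
]

#: Default cap on the order of any iterated level; prolific graphs grow
#: without bound, and the guard turns runaway growth into a clean diagnostic.
DEFAULT_VERTEX_BUDGET = 100_000


def edge_label(a: str, b: str) -> str:
    """Canonical label of the line-graph vertex created from edge {a, b}.

    Nested parenthesized labels accumulate across levels, e.g.
    ``((1,2),(2,3))`` for a bend built from bonds (1,2) and (2,3).
    """
    return f"({a},{b})"


@dataclass(frozen=True)
class LineGraphLevel:
    """L^level(G) plus the bijection back to the edges of the previous level.

    ``parent_edge_map`` maps each vertex label of this level to the ordered
    endpoint pair of the parent edge it was created from (None at level 0).
    """

    level: int
    graph: MolecularGraph
    parent_edge_map: dict[str, tuple[str, str]] | None


def _transform(g: MolecularGraph) -> tuple[MolecularGraph, dict[str, tuple[str, str]]]:
    """One application of L, combinatorial route (shared endpoints)."""
    if g.q == 0:
        raise GraphValidationError("line graph undefined for a graph with no edges")
    labels = [edge_label(a, b) for a, b in g.edges]
    parent_map = dict(zip(labels, g.edges))
    incident: dict[str, list[str]] = {v: [] for v in g.vertices}
    for lab, (a, b) in zip(labels, g.edges):
        incident[a].append(lab)
        incident[b].append(lab)
    lg_edges = []
    for v in g.vertices:
        labs = incident[v]
        # two distinct edges of a simple graph share at most one endpoint,
        # so each line-graph edge arises from exactly one common vertex
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                lg_edges.append((labs[i], labs[j]))
    lg = MolecularGraph.from_edges(lg_edges, vertices=labels)
    return lg, parent_map


def line_graph(g: MolecularGraph) -> LineGraphLevel:
    """Compute L(G) with vertex labels inherited from the edges of G."""
    lg, pmap = _transform(g)
    return LineGraphLevel(level=1, graph=lg, parent_edge_map=pmap)


def adjacency_from_incidence(g: MolecularGraph) -> np.ndarray:
    """A(L(G)) = Z^T Z - 2 I, the algebraic route to the line graph."""
    Z = matrices(g).incidence
    return Z.T @ Z - 2 * np.eye(g.q, dtype=np.int64)


@dataclass(frozen=True)
class IterationResult:
    """Levels 0..n of the iteration, possibly truncated early.

    ``reason`` is ``"budget"`` when the next level would exceed the vertex
    budget and ``"exhausted"`` when the current level has no edges (path
    graphs shrink to the null graph).
    """

    levels: tuple[LineGraphLevel, ...]
    truncated: bool
    reason: str | None


def iterate(
    g: MolecularGraph,
    n_max: int,
    vertex_budget: int = DEFAULT_VERTEX_BUDGET,
) -> IterationResult:
    """Compute L^0(G) ... L^{n_max}(G), truncating on budget or exhaustion."""
    if n_max < 0:
        raise ValueError("n_max must be non-negative")
    if vertex_budget < g.p:
        raise ValueError("vertex_budget must be at least the order of G")
    levels = [LineGraphLevel(0, g, None)]
    truncated, reason = False, None
    for n in range(1, n_max + 1):
        cur = levels[-1].graph
        if cur.q == 0:
            truncated, reason = True, "exhausted"
            break
        if cur.q > vertex_budget:
            truncated, reason = True, "budget"
            break
        nxt, pmap = _transform(cur)
        levels.append(LineGraphLevel(n, nxt, pmap))
    return IterationResult(tuple(levels), truncated, reason)


@dataclass(frozen=True)
class LimitClass:
    """Asymptotic fate of L^n(G): cycle, claw, path (with order) or prolific."""

    kind: str
    path_order: int | None = None


def classify_limit(g: MolecularGraph) -> LimitClass:
    """Classify the n -> infinity outcome of the iteration for connected G."""
    degs = sorted(g.degrees)
    if g.p >= 3 and all(d == 2 for d in degs):
        return LimitClass("cycle")
    if degs == [1, 1, 1, 3]:
        return LimitClass("claw")
    if g.p <= 2 or (degs.count(1) == 2 and degs.count(2) == g.p - 2):
        return LimitClass("path", path_order=g.p)
    return LimitClass("prolific")


@dataclass(frozen=True)
class LineIndexResult:
    """xi(G) plus the per-level planarity verdicts that established it.

    ``xi is None`` means the index is infinite: every iterate is planar,
    which happens exactly for the non-prolific limit classes.
    """

    xi: int | None
    planar_levels: tuple[bool, ...]

    @property
    def is_infinite(self) -> bool:
        return self.xi is None

    def __str__(self) -> str:
        return "infinite" if self.xi is None else str(self.xi)


def line_index(g: MolecularGraph, max_levels: int = 6) -> LineIndexResult:
    """Least m with L^m(G) nonplanar, via a certified linear-time planarity test.

    Non-prolific graphs are answered immediately (all their iterates are
    planar).  For a prolific graph the cited bound guarantees xi <= 4, so
    exceeding ``max_levels`` indicates an implementation bug and raises.
    """
    if classify_limit(g).kind != "prolific":
        return LineIndexResult(xi=None, planar_levels=())
    cur = g
    verdicts: list[bool] = []
    for m in range(max_levels + 1):
        is_planar, _ = nx.check_planarity(cur.to_networkx())
        verdicts.append(is_planar)
        if not is_planar:
            return LineIndexResult(xi=m, planar_levels=tuple(verdicts))
        cur = _transform(cur)[0]
    raise InternalConsistencyError(
        f"prolific graph remained planar through L^{max_levels}, violating the xi <= 4 bound"
    )
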