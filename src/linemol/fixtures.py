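"""Deterministic fixture graphs: named families and seeded random molecules.

The named families (paths, cycles, the claw, complete graphs) are the
graphs whose iterated line graphs have known fates, which makes them the
natural test bed.  ``random_connected`` emulates an arbitrary single
molecule: a uniform random spanning tree (so every tree topology is
reachable) plus k distinct extra edges, giving q = (p - 1) + k bonds and
controllable cyclomatic complexity.  A single integer seed controls all
randomness; identical spec and seed give an identical graph.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .graph_core import MolecularGraph

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "path_graph",
    "cycle_graph",
    "claw_graph",
    "complete_graph",
    "random_connected",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for one fixture graph.

    ``r`` sizes the named families; ``p`` and ``extra_edges`` size the
    random family.
    """

    family: str
    r: int | None = None
    p: int | None = None
    extra_edges: int = 0
    seed: int | None = None


def path_graph(r: int) -> MolecularGraph:
    """P_r: r vertices chained by r - 1 edges (two terminals of degree 1)."""
    if r < 1:
        raise ValueError("path order must be >= 1")
    verts = [str(i) for i in range(1, r + 1)]
    edges = [(verts[i], verts[i + 1]) for i in range(r - 1)]
    return MolecularGraph.from_edges(edges, vertices=verts)


def cycle_graph(r: int) -> MolecularGraph:
    """C_r: a closed chain of r >= 3 vertices, all of degree 2."""
    if r < 3:
        raise ValueError("cycle order must be >= 3")
    verts = [str(i) for i in range(1, r + 1)]
    edges = [(verts[i], verts[(i + 1) % r]) for i in range(r)]
    return MolecularGraph.from_edges(edges, vertices=verts)


def claw_graph() -> MolecularGraph:
    """K_{1,3}: one hub of degree 3 and three leaves."""
    return MolecularGraph.from_edges([("1", "2"), ("1", "3"), ("1", "4")])


def complete_graph(r: int) -> MolecularGraph:
    """K_r on r >= 2 vertices."""
    if r < 2:
        raise ValueError("complete graph order must be >= 2")
    verts = [str(i) for i in range(1, r + 1)]
    return MolecularGraph.from_edges(combinations(verts, 2), vertices=verts)


def random_connected(p: int, extra_edges: int = 0, seed: int | None = None) -> MolecularGraph:
    """Connected simple graph: uniform spanning tree plus extra edges.

    The tree is drawn uniformly over all labelled trees on p vertices; the
    ``extra_edges`` non-tree edges are then sampled without replacement.
    """
    if p < 2:
        raise ValueError("random connected graph needs p >= 2")
    max_extra = p * (p - 1) // 2 - (p - 1)
    if extra_edges < 0 or extra_edges > max_extra:
        raise ValueError(f"extra_edges must be in [0, {max_extra}] for p={p}")
    rng = random.Random(seed)
    tree = nx.random_labeled_tree(p, seed=rng)
    tree_edges = {(min(u, v), max(u, v)) for u, v in tree.edges}
    pool = sorted(set(combinations(range(p), 2)) - tree_edges)
    extras = rng.sample(pool, extra_edges)
    edges = [(str(u + 1), str(v + 1)) for u, v in sorted(tree_edges) + sorted(extras)]
    return MolecularGraph.from_edges(edges)


def make_fixture(spec: FixtureSpec) -> MolecularGraph:
    """Dispatch a :class:`FixtureSpec` to its family builder."""
    if spec.family == "path":
        return path_graph(spec.r or 0)
    if spec.family == "cycle":
        return cycle_graph(spec.r or 0)
    if spec.family == "claw":
        return claw_graph()
    if spec.family == "complete":
        return complete_graph(spec.r or 0)
    if spec.family == "random_connected":
        if spec.p is None:
            raise ValueError("random_connected requires p")
        return random_connected(spec.p, spec.extra_edges, spec.seed)
    raise ValueError(f"unknown fixture family {spec.family!r}")
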