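"""The interaction-hierarchy DAG, atomic index sequences and 4-body classification.

The recursion of line graphs is compactly represented by a weakly connected
nu-partite directed acyclic graph H_nu(G): level n holds the vertices of
L^{n-1}(G) (the n-body interactions), and each level-(n+1) vertex receives
exactly two arcs, one from each endpoint of the edge of L^{n-1}(G) it was
created from.  The full adjacency matrix of H_nu(G) is block tridiagonal
with off-diagonal blocks given by the incidence matrices Z(L^{n-1}(G)).

Backtracking a level-n vertex through its two parents down to the atoms
yields a sequence of 2^{n-1} atomic indexes.  The multiset multiplicity
pattern of the 8-index sequence classifies every 4-body interaction:

* two triply repeated indexes and two singletons  -> proper torsion,
* one quadruply repeated index (the single hinge) -> improper dihedral,
* only three distinct indexes (pattern 3+3+2)     -> degenerate 3-cycle.

Each improper and each triangle occurs as three rotational sequence
variants (one per choice of the shared bond); deduplication collapses them
into one physical record with a shared variant group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx

from .errors import BudgetExceededError, GraphValidationError, InternalConsistencyError
from .graph_core import MolecularGraph, matrices, require_connected
from .line_graph import DEFAULT_VERTEX_BUDGET, LineGraphLevel, iterate

__all__ = [
    "InteractionHierarchy",
    "InteractionRecord",
    "build_hierarchy",
    "backtrack_sequence",
    "classify_sequence",
    "interaction_table",
    "export_dag",
]

_SIGNATURES = {
    (3, 3, 1, 1): "proper",
    (4, 2, 1, 1): "improper",
    (3, 3, 2): "three_cycle",
}

_ORDER_TYPES = {1: "atom", 2: "bond", 3: "bend"}


@dataclass(frozen=True)
class InteractionHierarchy:
    """H_nu(G): levels of iterated line graphs plus the two-parent arcs.

    ``levels[k]`` is L^k(G), so DAG level n corresponds to ``levels[n-1]``.
    ``dag`` has nodes ``(n, label)``; arcs run only between consecutive
    levels.  For path-family graphs the hierarchy may hold fewer than nu
    levels because the iteration exhausts.
    """

    nu: int
    source: MolecularGraph
    levels: tuple[LineGraphLevel, ...]
    dag: nx.DiGraph

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_vertices(self, n: int) -> tuple[str, ...]:
        """Vertex labels of DAG level n (1-based)."""
        return self.levels[n - 1].graph.vertices


def build_hierarchy(
    g: MolecularGraph,
    nu: int = 4,
    vertex_budget: int = DEFAULT_VERTEX_BUDGET,
) -> InteractionHierarchy:
    """Assemble H_nu(G) from the iterated line graphs."""
    require_connected(g)
    if nu < 1:
        raise ValueError("maximum interaction order nu must be >= 1")
    res = iterate(g, nu - 1, vertex_budget)
    if res.truncated and res.reason == "budget":
        raise BudgetExceededError(
            f"vertex budget {vertex_budget} exhausted before level {nu} of the hierarchy"
        )
    dag = nx.DiGraph()
    for lvl in res.levels:
        n = lvl.level + 1  # DAG levels are 1-based interaction orders
        for lab in lvl.graph.vertices:
            dag.add_node((n, lab), level=n)
        if lvl.parent_edge_map is not None:
            for lab, (a, b) in lvl.parent_edge_map.items():
                dag.add_edge((n - 1, a), (n, lab))
                dag.add_edge((n - 1, b), (n, lab))
    return InteractionHierarchy(nu=nu, source=g, levels=res.levels, dag=dag)


def backtrack_sequence(h: InteractionHierarchy, n: int, label: str) -> tuple[str, ...]:
    """Atomic index sequence (length 2^{n-1}) of the level-n vertex ``label``.

    The sequence is the concatenation of the two parents' sequences; the
    parent with the smaller canonical label contributes the left half.
    Level-1 vertices are atoms and return themselves.
    """
    if (n, label) not in h.dag:
        raise GraphValidationError(f"no vertex {label!r} at hierarchy level {n}")
    cache: dict[tuple[int, str], tuple[str, ...]] = {}

    def back(level: int, lab: str) -> tuple[str, ...]:
        key = (level, lab)
        if key in cache:
            return cache[key]
        if level == 1:
            seq: tuple[str, ...] = (lab,)
        else:
            pmap = h.levels[level - 1].parent_edge_map
            if pmap is None or lab not in pmap:
                raise InternalConsistencyError(f"dangling vertex {lab!r} at level {level}")
            a, b = pmap[lab]  # already ordered by the parent level's vertex order
            seq = back(level - 1, a) + back(level - 1, b)
        cache[key] = seq
        return seq

    return back(n, label)


def classify_sequence(seq: tuple[str, ...]) -> str:
    """Classify an 8-index sequence by its sorted multiplicity signature."""
    if len(seq) != 8:
        raise ValueError(f"4-body classification needs a sequence of length 8, got {len(seq)}")
    sig = tuple(sorted(Counter(seq).values(), reverse=True))
    try:
        return _SIGNATURES[sig]
    except KeyError:
        raise InternalConsistencyError(
            f"multiplicity signature {sig} is impossible for a simple-graph hierarchy"
        ) from None


@dataclass(frozen=True)
class InteractionRecord:
    """One interaction: order, raw backtracked sequence, type, participants.

    ``participants`` is the canonical atom tuple (see the conventions in
    :func:`interaction_table`); ``variant_group`` is shared by the three
    rotational variants of one improper or 3-cycle and is None otherwise.
    """

    order: int
    sequence: tuple[str, ...]
    itype: str
    participants: tuple[str, ...]
    variant_group: str | None = None


def _canonical_participants(
    g: MolecularGraph, order: int, itype: str, seq: tuple[str, ...]
) -> tuple[str, ...]:
    """Canonical participant tuple, deterministic under the vertex order of G.

    Conventions: bend (i, j, k) with hinge j and i < k; proper (i, j, k, l)
    with hinge bond {j, k}, oriented to the lexicographically smaller of the
    two traversal directions; improper hinge first then sorted periphery;
    3-cycle sorted.
    """
    skey = lambda lab: g.index(lab)
    counts = Counter(seq)
    if order == 1:
        return (seq[0],)
    if order == 2:
        return tuple(sorted(counts, key=skey))
    if order == 3:
        hinge = next(lab for lab, c in counts.items() if c == 2)
        ends = sorted((lab for lab in counts if lab != hinge), key=skey)
        return (ends[0], hinge, ends[1])
    if order == 4:
        if itype == "proper":
            hinges = [lab for lab, c in counts.items() if c == 3]
            singles = [lab for lab, c in counts.items() if c == 1]
            nbrs = g.neighbor_sets
            candidates = [
                (x, a, b, y)
                for x, y in (singles, singles[::-1])
                for a, b in (hinges, hinges[::-1])
                if x in nbrs[a] and y in nbrs[b]
            ]
            if not candidates:
                raise InternalConsistencyError(f"proper sequence {seq} admits no 4-path layout")
            return min(candidates, key=lambda t: tuple(skey(x) for x in t))
        if itype == "improper":
            hinge = next(lab for lab, c in counts.items() if c == 4)
            periphery = sorted((lab for lab in counts if lab != hinge), key=skey)
            return (hinge, *periphery)
        if itype == "three_cycle":
            return tuple(sorted(counts, key=skey))
    return tuple(sorted(counts, key=skey))  # unclassified higher orders


def interaction_table(
    g: MolecularGraph,
    nu: int = 4,
    dedupe: bool = True,
    vertex_budget: int = DEFAULT_VERTEX_BUDGET,
) -> list[InteractionRecord]:
    """All interactions of order 1..nu as canonical records.

    One record per DAG vertex per level (levels are cumulative, as in a
    simulation topology).  With ``dedupe`` the three rotational variants of
    each improper and each 3-cycle collapse into a single physical record;
    orders above 4 are emitted unclassified with raw sequences only.
    """
    h = build_hierarchy(g, nu, vertex_budget)
    skey = lambda lab: g.index(lab)
    records: list[InteractionRecord] = []
    for n in range(1, h.n_levels + 1):
        for lab in h.level_vertices(n):
            seq = backtrack_sequence(h, n, lab)
            if n in _ORDER_TYPES:
                itype = _ORDER_TYPES[n]
            elif n == 4:
                itype = classify_sequence(seq)
            else:
                itype = "unclassified"
            participants = _canonical_participants(g, n, itype, seq)
            group = (
                f"{itype}:" + "-".join(participants)
                if itype in ("improper", "three_cycle")
                else None
            )
            records.append(InteractionRecord(n, seq, itype, participants, group))

    if dedupe:
        deduped: list[InteractionRecord] = []
        groups: dict[str, int] = {}
        for rec in records:
            if rec.variant_group is None:
                deduped.append(rec)
            elif rec.variant_group not in groups:
                groups[rec.variant_group] = 1
                deduped.append(rec)
            else:
                groups[rec.variant_group] += 1
        bad = {k: v for k, v in groups.items() if v != 3}
        if bad:
            raise InternalConsistencyError(
                f"rotational variant groups without exactly 3 members: {bad}"
            )
        records = deduped

    records.sort(key=lambda r: (r.order, tuple(skey(x) for x in r.participants), r.itype))
    return records


def export_dag(h: InteractionHierarchy, format: str = "dot") -> str:
    """Serialize H_nu(G) as DOT, GraphML, or a TSV of the incidence blocks.

    The TSV variant lists every vertex with its level, then the
    block-tridiagonal structure row by row: block n is Z(L^{n-1}(G)), the
    incidence matrix linking level n to level n+1.
    """
    if format == "dot":
        lines = ["digraph interaction_hierarchy {", "  rankdir=LR;"]
        for n, lab in h.dag.nodes:
            lines.append(f'  "{n}:{lab}" [label="{lab}" level={n}];')
        for (n1, a), (n2, b) in h.dag.edges:
            lines.append(f'  "{n1}:{a}" -> "{n2}:{b}";')
        lines.append("}")
        return "\n".join(lines) + "\n"
    if format == "graphml":
        out = nx.DiGraph()
        for n, lab in h.dag.nodes:
            out.add_node(f"{n}:{lab}", level=n, label=lab)
        for (n1, a), (n2, b) in h.dag.edges:
            out.add_edge(f"{n1}:{a}", f"{n2}:{b}")
        return "\n".join(nx.generate_graphml(out)) + "\n"
    if format == "tsv":
        lines = ["# section\tlevel\tlabel_or_row"]
        for n in range(1, h.n_levels + 1):
            for lab in h.level_vertices(n):
                lines.append(f"vertex\t{n}\t{lab}")
        for n in range(1, h.n_levels):
            Z = matrices(h.levels[n - 1].graph).incidence
            for i, row in enumerate(Z):
                cells = "\t".join(str(int(x)) for x in row)
                lines.append(f"block_Z(L^{n - 1})_row{i}\t{n}\t{cells}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown DAG export format {format!r}")
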