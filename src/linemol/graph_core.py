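"""Molecular connectivity graphs and their standard matrix representations.

A molecule's bonded topology is modelled as a simple, loopless, undirected
graph: atoms (or coarse-grained beads) are vertices and covalent bonds are
edges.  This module provides the :class:`MolecularGraph` container together
with the matrices of algebraic graph theory used throughout the package:

* ``A`` — the p x p binary vertex adjacency matrix,
* ``Z`` — the p x q binary vertex-edge incidence matrix,
* ``D`` — the diagonal degree (valency) matrix,
* ``K = D - A`` — the Kirchhoff (Laplacian) matrix, whose rank is p - c
  for a graph with c connected components,
* ``Q = A + D = Z Z^T`` — the signless Laplacian.

Entry ``(A^m)_{ij}`` counts the m-step walks from vertex i to vertex j,
which is the algebraic fact underlying all the interaction-count formulas
in :mod:`linemol.enumeration`.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from fractions import Fraction
from functools import cached_property
from typing import Iterable, Sequence, TextIO, Union

import networkx as nx
import numpy as np

from .errors import GraphParseError, GraphValidationError, InternalConsistencyError

__all__ = [
    "MolecularGraph",
    "GraphMatrices",
    "ValidationReport",
    "read_graph",
    "write_graph",
    "validate",
    "matrices",
    "require_connected",
]

#: Numeric rank tolerance (relative to the largest singular value) used for
#: graphs too large for exact elimination.
_NUMERIC_RANK_TOL = 1e-9

#: Largest order for which the Kirchhoff rank is computed by exact
#: fraction-free elimination; chemical graphs are essentially always below it.
_EXACT_RANK_MAX_P = 64


def _natural_sort_key(labels: Iterable[str]):
    """Return a sort key for vertex labels.

    When every label parses as an integer the order is numeric (so that the
    atom labels ``1, 2, ..., 12`` sort as a chemist expects); otherwise the
    order is plain lexicographic.
    """
    labels = list(labels)
    try:
        as_int = {lab: int(lab) for lab in labels}
    except ValueError:
        return lambda lab: lab
    return lambda lab: as_int[lab]


@dataclass(frozen=True)
class MolecularGraph:
    """A labelled simple undirected graph in canonical order.

    ``vertices`` is the canonical vertex order (positions define the row
    order of every matrix); ``edges`` is the canonical edge order:
    lexicographic by (min endpoint, max endpoint) position.  Construct via
    :meth:`from_edges`, which canonicalizes; the raw constructor expects
    already-canonical input and only checks hard invariants.
    """

    vertices: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.vertices)) != len(self.vertices):
            raise GraphValidationError("duplicate vertex labels")
        known = set(self.vertices)
        seen: set[tuple[str, str]] = set()
        for a, b in self.edges:
            if a == b:
                raise GraphValidationError(f"loop edge ({a}, {b}) is forbidden")
            if a not in known or b not in known:
                raise GraphValidationError(f"edge ({a}, {b}) references unknown vertex")
            key = (a, b) if a < b else (b, a)
            if key in seen:
                raise GraphValidationError(f"duplicate edge ({a}, {b})")
            seen.add(key)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Sequence],
        vertices: Sequence | None = None,
    ) -> "MolecularGraph":
        """Build a graph in canonical vertex and edge order.

        Vertex labels are opaque strings (any input label is passed through
        ``str``).  If ``vertices`` is given its order is preserved verbatim
        (this is how line-graph levels keep the parent edge order);
        otherwise labels are collected from the edges and sorted naturally.
        """
        raw = [(str(a), str(b)) for a, b in edges]
        for a, b in raw:
            if a == b:
                raise GraphValidationError(f"loop edge ({a}, {b}) is forbidden")
        if vertices is None:
            labels = sorted({lab for e in raw for lab in e}, key=_natural_sort_key({lab for e in raw for lab in e}))
        else:
            labels = [str(v) for v in vertices]
        index = {lab: i for i, lab in enumerate(labels)}
        for a, b in raw:
            if a not in index or b not in index:
                raise GraphValidationError(f"edge ({a}, {b}) references unknown vertex")
        canon = []
        seen = set()
        for a, b in raw:
            e = (a, b) if index[a] < index[b] else (b, a)
            if e in seen:
                raise GraphValidationError(f"duplicate edge ({a}, {b})")
            seen.add(e)
            canon.append(e)
        canon.sort(key=lambda e: (index[e[0]], index[e[1]]))
        return cls(tuple(labels), tuple(canon))

    # -- basic accessors ---------------------------------------------------

    @property
    def p(self) -> int:
        """Order: number of vertices (atoms)."""
        return len(self.vertices)

    @property
    def q(self) -> int:
        """Size: number of edges (bonds)."""
        return len(self.edges)

    @cached_property
    def _index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.vertices)}

    def index(self, label: str) -> int:
        """Position of ``label`` in the canonical vertex order."""
        return self._index[label]

    @cached_property
    def neighbor_sets(self) -> dict[str, frozenset[str]]:
        """Neighbor set S_i for every vertex."""
        nbrs: dict[str, set[str]] = {v: set() for v in self.vertices}
        for a, b in self.edges:
            nbrs[a].add(b)
            nbrs[b].add(a)
        return {v: frozenset(s) for v, s in nbrs.items()}

    def degree(self, label: str) -> int:
        return len(self.neighbor_sets[label])

    @cached_property
    def degrees(self) -> tuple[int, ...]:
        """Degree sequence in canonical vertex order."""
        return tuple(len(self.neighbor_sets[v]) for v in self.vertices)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class GraphMatrices:
    """The five matrix representations of a molecular graph (integer dtype)."""

    adjacency: np.ndarray
    incidence: np.ndarray
    degree: np.ndarray
    kirchhoff: np.ndarray
    signless_laplacian: np.ndarray


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of structural validation.

    Connectivity is computed two independent ways — the rank of the
    Kirchhoff matrix must equal p - 1, and a graph traversal must reach all
    vertices — and the two verdicts are required to agree.
    """

    loopless: bool
    simple: bool
    covering: bool
    kirchhoff_rank: int
    connected_by_rank: bool
    connected_by_traversal: bool

    @property
    def connected(self) -> bool:
        return self.connected_by_rank and self.connected_by_traversal

    @property
    def ok(self) -> bool:
        return self.loopless and self.simple and self.covering and self.connected


# -- parsing / serialization ----------------------------------------------


def _read_edge_list(text: str) -> MolecularGraph:
    edges = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphParseError(
                f"line {lineno}: expected two whitespace-separated vertex labels, got {len(parts)}"
            )
        edges.append((parts[0], parts[1]))
    if not edges:
        raise GraphParseError("edge list contains no edges")
    return MolecularGraph.from_edges(edges)


def _read_adjacency_csv(text: str) -> MolecularGraph:
    rows = [row for row in csv.reader(io.StringIO(text)) if any(c.strip() for c in row)]
    if not rows:
        raise GraphParseError("empty adjacency input")

    # a header row is present exactly when there is one more row than columns
    ncols = len(rows[0])
    if len(rows) == ncols + 1:
        labels = [c.strip() for c in rows[0]]
        data = rows[1:]
    else:
        labels = [str(i + 1) for i in range(ncols)]
        data = rows
    p = len(labels)
    if len(data) != p or any(len(r) != p for r in data):
        raise GraphParseError(f"adjacency matrix is not square ({len(data)} rows, {p} columns expected)")
    mat = np.zeros((p, p), dtype=np.int64)
    for i, row in enumerate(data):
        for j, cell in enumerate(row):
            cell = cell.strip()
            if cell not in {"0", "1"}:
                raise GraphParseError(f"non-binary adjacency entry {cell!r} at row {i + 1}, column {j + 1}")
            mat[i, j] = int(cell)
    if np.any(mat != mat.T):
        raise GraphParseError("adjacency matrix is not symmetric")
    if np.any(np.diag(mat) != 0):
        raise GraphParseError("adjacency matrix has a nonzero diagonal (loops are forbidden)")
    edges = [(labels[i], labels[j]) for i in range(p) for j in range(i + 1, p) if mat[i, j]]
    order = sorted(labels, key=_natural_sort_key(labels))
    return MolecularGraph.from_edges(edges, vertices=order)


def read_graph(source: Union[str, TextIO], format: str = "edge_list") -> MolecularGraph:
    """Parse a molecular graph from text.

    ``source`` is either the text itself or a readable text stream.
    Formats: ``edge_list`` (one unordered pair per line, ``#`` comments and
    blank lines allowed) or ``adjacency_csv`` (square binary symmetric
    matrix, optional header row of vertex labels).
    """
    text = source if isinstance(source, str) else source.read()
    if format == "edge_list":
        return _read_edge_list(text)
    if format == "adjacency_csv":
        return _read_adjacency_csv(text)
    raise ValueError(f"unknown graph format {format!r}")


def write_graph(g: MolecularGraph, format: str = "edge_list") -> str:
    """Serialize ``g``; the edge_list form round-trips bit-identically."""
    if format == "edge_list":
        return "".join(f"{a} {b}\n" for a, b in g.edges)
    if format == "adjacency_csv":
        m = matrices(g)
        lines = [",".join(g.vertices)]
        lines += [",".join(str(x) for x in row) for row in m.adjacency]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown graph format {format!r}")


# -- matrices and validation ----------------------------------------------


def matrices(g: MolecularGraph) -> GraphMatrices:
    """Compute A, Z, D, K and Q in the canonical vertex/edge order of ``g``."""
    p, q = g.p, g.q
    A = np.zeros((p, p), dtype=np.int64)
    Z = np.zeros((p, q), dtype=np.int64)
    for alpha, (a, b) in enumerate(g.edges):
        i, j = g.index(a), g.index(b)
        A[i, j] = A[j, i] = 1
        Z[i, alpha] = Z[j, alpha] = 1
    D = np.diag(A.sum(axis=1))
    return GraphMatrices(
        adjacency=A,
        incidence=Z,
        degree=D,
        kirchhoff=D - A,
        signless_laplacian=A + D,
    )


def _exact_rank(mat: np.ndarray) -> int:
    """Rank over the rationals by Gauss elimination with exact Fractions."""
    rows = [[Fraction(int(x)) for x in row] for row in mat]
    nrows = len(rows)
    ncols = len(rows[0]) if nrows else 0
    rank = 0
    for col in range(ncols):
        pivot = next((r for r in range(rank, nrows) if rows[r][col] != 0), None)
        if pivot is None:
            continue
        rows[rank], rows[pivot] = rows[pivot], rows[rank]
        pv = rows[rank][col]
        for r in range(nrows):
            if r != rank and rows[r][col] != 0:
                f = rows[r][col] / pv
                rows[r] = [x - f * y for x, y in zip(rows[r], rows[rank])]
        rank += 1
        if rank == nrows:
            break
    return rank


def kirchhoff_rank(g: MolecularGraph) -> int:
    """Rank of K(G): exact for small graphs, SVD-based above p = 64."""
    K = matrices(g).kirchhoff
    if g.p == 0:
        return 0
    if g.p <= _EXACT_RANK_MAX_P:
        return _exact_rank(K)
    sv = np.linalg.svd(K.astype(float), compute_uv=False)
    return int(np.sum(sv > _NUMERIC_RANK_TOL * sv.max())) if sv.size else 0


def validate(g: MolecularGraph) -> ValidationReport:
    """Structural validation; connectivity checked by rank and by traversal."""
    covering = all(g.degree(v) >= 1 for v in g.vertices) and g.p > 0
    rank = kirchhoff_rank(g)
    by_rank = g.p > 0 and rank == g.p - 1
    gnx = g.to_networkx()
    by_traversal = g.p > 0 and nx.is_connected(gnx)
    if by_rank != by_traversal:
        raise InternalConsistencyError(
            f"connectivity verdicts disagree: rank(K)={rank} vs traversal={by_traversal}"
        )
    return ValidationReport(
        loopless=True,
        simple=True,
        covering=covering,
        kirchhoff_rank=rank,
        connected_by_rank=by_rank,
        connected_by_traversal=by_traversal,
    )


def require_connected(g: MolecularGraph) -> None:
    """Refuse disconnected (or vertex-non-covering) input.

    Enumeration and hierarchy operations treat one molecule per graph;
    multi-molecule input must be split by the caller.
    """
    report = validate(g)
    if not report.covering:
        raise GraphValidationError("graph has isolated vertices (every atom must occur in a bond)")
    if not report.connected:
        raise GraphValidationError(
            f"graph is disconnected (rank K = {report.kirchhoff_rank}, expected p - 1 = {g.p - 1})"
        )
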