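"""Closed-form interaction counts, the line-graph route, and a brute-force oracle.

For a connected molecular graph G with adjacency A, degree matrix D,
signless Laplacian Q = A + D and all-ones vector u, the n-body interaction
counts are (with N_n(G) = |V(L^{n-1}(G))| in general):

* N_1 = p                              (atoms)
* N_2 = N_bond = (1/2) Tr D = q        (bonds; handshaking lemma)
* N_3 = N_bend = (1/2) u'D^2 u - N_2   (= sum_v C(deg v, 2))
* N_impr = (1/6) u'D^3 u - N_3 - N_2/3 (= sum_v C(deg v, 3))
* N_prop + 3 N_3cyc = (1/2) u'D A D u - 2 N_3 - N_2
* N_3cyc = (1/6) Tr A^3               (triangles)
* N_4 = N_prop + 3 N_impr + 3 N_3cyc  (rotational variants counted 3x)

with the independent checksum N_4 = (1/2) u'D Q D u - 5 N_3 - 2 N_2.

All arithmetic is exact: the fractional coefficients are applied as
rational steps and a non-integer intermediate raises — it can only mean a
formula was misapplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations

import numpy as np

from .errors import BudgetExceededError, InternalConsistencyError
from .graph_core import MolecularGraph, matrices, require_connected
from .line_graph import DEFAULT_VERTEX_BUDGET, iterate

__all__ = ["CountSummary", "closed_form_counts", "brute_force_counts", "count_via_line_graphs"]

#: Largest order accepted by the brute-force subgraph oracle.
_ORACLE_MAX_P = 64


@dataclass(frozen=True)
class CountSummary:
    """All interaction counts for one molecular graph.

    ``n_impr`` and ``n_3cyc`` are the deduplicated physical counts; the
    3x rotational variants appear only inside ``n4``.
    """

    n1: int
    n2: int
    n3: int
    n4: int
    n_prop: int
    n_impr: int
    n_3cyc: int
    checksums: dict[str, bool] = field(default_factory=dict)

    @property
    def checksum_pass(self) -> bool:
        return all(self.checksums.values())

    def counts_dict(self) -> dict[str, int]:
        return {
            "n1": self.n1,
            "n2": self.n2,
            "n3": self.n3,
            "n4": self.n4,
            "n_prop": self.n_prop,
            "n_impr": self.n_impr,
            "n_3cyc": self.n_3cyc,
        }


def _as_int(x: Fraction, what: str) -> int:
    if x.denominator != 1:
        raise InternalConsistencyError(f"{what} evaluated to the non-integer {x}")
    if x < 0:
        raise InternalConsistencyError(f"{what} evaluated to the negative value {x}")
    return int(x)


def closed_form_counts(g: MolecularGraph) -> CountSummary:
    """Interaction counts from G alone, with the quadratic-form checksum.

    Any disagreement between two formulas raises
    :class:`~linemol.errors.InternalConsistencyError`.
    """
    require_connected(g)
    degs = g.degrees
    A = matrices(g).adjacency

    n1 = g.p
    n2 = Fraction(sum(degs), 2)
    n3 = Fraction(sum(d * d for d in degs), 2) - n2
    n_impr = Fraction(sum(d**3 for d in degs), 6) - n3 - n2 / 3
    # u'D A D u = sum_{ij} d_i A_ij d_j = 2 * sum_{edges} d_a d_b
    u_dad_u = 2 * sum(g.degree(a) * g.degree(b) for a, b in g.edges)
    prop_plus_3cyc = Fraction(u_dad_u, 2) - 2 * n3 - n2
    tr_a3 = int(np.trace(np.linalg.matrix_power(A, 3)))
    n_3cyc = Fraction(tr_a3, 6)
    n_prop = prop_plus_3cyc - 3 * n_3cyc
    n4 = n_prop + 3 * n_impr + 3 * n_3cyc
    # independent checksum via the signless Laplacian: u'DQDu = u'DADu + u'D^3u
    n4_check = Fraction(u_dad_u + sum(d**3 for d in degs), 2) - 5 * n3 - 2 * n2

    checksums = {
        "handshake_n2_equals_q": n2 == g.q,
        "n4_signless_laplacian_form": n4 == n4_check,
    }
    summary = CountSummary(
        n1=n1,
        n2=_as_int(n2, "N_2"),
        n3=_as_int(n3, "N_3"),
        n4=_as_int(n4, "N_4"),
        n_prop=_as_int(n_prop, "N_prop"),
        n_impr=_as_int(n_impr, "N_impr"),
        n_3cyc=_as_int(n_3cyc, "N_3cyc"),
        checksums=checksums,
    )
    if not summary.checksum_pass:
        failed = [k for k, v in checksums.items() if not v]
        raise InternalConsistencyError(f"count checksums failed: {failed}")
    return summary


def brute_force_counts(g: MolecularGraph) -> CountSummary:
    """Independent oracle: count interactions by direct subgraph enumeration.

    Deliberately shares no formula with :func:`closed_form_counts` — bends
    are enumerated as edge pairs at a common vertex, impropers as edge
    triples at a common vertex, propers as simple 4-vertex paths and
    triangles as 3-cliques.
    """
    require_connected(g)
    if g.p > _ORACLE_MAX_P:
        raise ValueError(f"brute-force oracle limited to p <= {_ORACLE_MAX_P} (got p={g.p})")
    nbrs = g.neighbor_sets

    n_bend = sum(1 for v in g.vertices for _pair in combinations(sorted(nbrs[v]), 2))
    n_impr = sum(1 for v in g.vertices for _tri in combinations(sorted(nbrs[v]), 3))

    n_prop = 0
    for j, k in g.edges:  # middle bond of the 4-path, orientation fixed by canonical edge
        for i in nbrs[j] - {k}:
            for l in nbrs[k] - {j}:
                if i != l:
                    n_prop += 1

    n_3cyc = 0
    verts = list(g.vertices)
    for a, b, c in combinations(verts, 3):
        if b in nbrs[a] and c in nbrs[a] and c in nbrs[b]:
            n_3cyc += 1

    return CountSummary(
        n1=g.p,
        n2=g.q,
        n3=n_bend,
        n4=n_prop + 3 * n_impr + 3 * n_3cyc,
        n_prop=n_prop,
        n_impr=n_impr,
        n_3cyc=n_3cyc,
    )


def count_via_line_graphs(
    g: MolecularGraph,
    n: int,
    vertex_budget: int = DEFAULT_VERTEX_BUDGET,
) -> int:
    """N_n(G) = |V(L^{n-1}(G))| by actually iterating the line graph.

    For n >= 2 the result is also computed as (1/2) Tr A^2(L^{n-2}(G)) and
    the two routes must agree.  Works for any order n, including n >= 5
    where no closed-form count is provided.
    """
    require_connected(g)
    if n < 1:
        raise ValueError("interaction order n must be >= 1")
    if n == 1:
        return g.p
    res = iterate(g, n - 1, vertex_budget)
    if len(res.levels) <= n - 1:
        if res.reason == "exhausted":
            return 0  # path family ran out of edges: no n-body terms remain
        raise BudgetExceededError(
            f"vertex budget {vertex_budget} exhausted before reaching L^{n - 1}(G)"
        )
    vertex_route = res.levels[n - 1].graph.p
    A_prev = matrices(res.levels[n - 2].graph).adjacency
    tr = int(np.trace(A_prev @ A_prev))
    trace_route = _as_int(Fraction(tr, 2), f"(1/2) Tr A^2(L^{n - 2})")
    if vertex_route != trace_route:
        raise InternalConsistencyError(
            f"N_{n} disagreement: |V(L^{n - 1})|={vertex_route} vs trace route {trace_route}"
        )
    return vertex_route
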