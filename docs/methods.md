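# Methods

## Model and assumptions

A molecule is represented purely by its bonded topology: a finite simple
undirected graph *G* with p vertices (atoms or coarse-grained beads) and q
edges (covalent bonds). Loops and multi-edges are rejected at
construction; connectivity and vertex coverage are enforced by every
enumeration/hierarchy operation, because the method treats one molecule
per graph. Splitting a multi-molecule system into components is the
caller's responsibility — no per-component escape hatch is offered, to
keep outputs unambiguous.

Connectivity is verified two independent ways and the verdicts must
agree: rank K(G) = p − 1 (the zero eigenvalue of the Kirchhoff matrix has
multiplicity equal to the number of components) and plain graph
traversal. The rank is computed by exact Fraction elimination for p ≤ 64
— small chemical graphs must never get a floating-point false verdict —
and by SVD with relative tolerance 1e-9 above that.

## Canonical orders

All outputs are deterministic and diff-stable:

- Vertex order: natural-numeric when every label parses as an integer
  (the common 1-based atom numbering), else lexicographic. Labels are
  opaque strings preserved verbatim from input.
- Edge order: lexicographic by (min endpoint, max endpoint) position.
- Line-graph vertex labels: the parent edge rendered `(a,b)` with a
  before b in the parent's vertex order, so nested labels such as
  `((1,2),(2,3))` accumulate across levels.
- Backtracking concatenates the parent with the smaller canonical label
  on the left. The 4-body classification depends only on the multiset of
  indexes, so this choice affects presentation, not typing.
- Canonical participant tuples: bend (i, j, k) with hinge j and i < k;
  proper (i, j, k, l) with the hinge bond {j, k} oriented to the
  lexicographically smaller traversal; improper hinge first, periphery
  sorted; 3-cycle sorted.

A consequence of choosing one canonical edge order is that a published
listing using a different edge numbering may print the two halves of a
nested label in the opposite order; interactions should therefore be
compared as unordered pairs of unordered pairs, which is what the
acceptance tests do.

## Dual routes and exact arithmetic

Wherever two derivations of the same quantity exist, both are computed
and compared, and disagreement raises immediately rather than being
swallowed:

- L(G) is built combinatorially (edges sharing an endpoint) and checked
  against Zᵀ Z − 2 I in the tests.
- N_n is computed from the closed forms, from |V(Lⁿ⁻¹(G))|, from
  ½ Tr A²(Lⁿ⁻²(G)), and from a brute-force subgraph oracle (edge pairs /
  edge triples at a vertex, simple 4-paths, 3-cliques) that shares no
  code with the formulas.
- The order-4 census of the DAG backtracking must reproduce N_prop,
  3 N_impr and 3 N_3cyc exactly.

Count arithmetic uses exact rationals; the coefficients ⅙ and ⅓ are
applied as Fractions with a final integrality assertion, since a
non-integer intermediate can only mean a formula was misapplied.

## Parameters

- `nu` (default 4): maximum interaction order. Orders 1–4 are classified
  (atom, bond, bend, proper/improper/3-cycle); higher orders are emitted
  with raw index sequences and type `unclassified`, because their
  sub-type taxonomy multiplies quickly and is not defined here.
- `vertex_budget` (default 100 000 vertices per level): prolific graphs
  grow without bound under iteration, and the guard converts runaway
  growth into a clean truncation status (`iterate`) or a
  `BudgetExceededError` (hierarchy, counts) rather than memory
  exhaustion.
- `max_levels` for the line index (default 6): prolific graphs satisfy
  0 ≤ ξ ≤ 4, so the cap is never reached by a correct implementation and
  exceeding it raises an internal-consistency error. Planarity per level
  uses networkx's certified linear-time left–right test; only the boolean
  verdict is consumed, no Kuratowski certificate is extracted.

## Fixture generator

`random_connected(p, k, seed)` emulates an arbitrary single molecule: a
uniform random labelled spanning tree (every tree topology reachable)
plus k distinct non-tree edges, so q = (p − 1) + k and the cyclomatic
number is exactly k. One integer seed controls all randomness;
identical parameters and seed give an identical graph. The generator
covers topology only: it does not emulate element types, bond orders,
realistic valence distributions or geometry, so passing property tests
demonstrates correctness of the combinatorics on arbitrary connected
topologies, not chemical plausibility of any particular sample. Property
tests run the three count routes over seeded families with p ≤ 12 (200
graphs in the acceptance suite), a scale at which the brute-force oracle
is instant yet degree patterns (terminals, hubs, fused rings) are all
exercised.

## Degenerate inputs and edge cases

- A single edge is the smallest valid molecule; its line graph is a
  single vertex with no edges, and iterating past an edgeless level
  truncates with status `exhausted` (path families shrink to the null
  graph; exhausted counts are 0).
- `line_graph` of an edgeless graph raises: the transformation is
  undefined there.
- Non-prolific limit classes (cycle, path, claw) short-circuit the line
  index to `infinite` without iterating.
- Adjacency-CSV input must be square, binary, symmetric and
  zero-diagonal; a header row is recognized purely by shape (rows =
  columns + 1).

## Known limitations

- No chemistry-format readers (MOL/SDF/PDB) and no bond orders, charges
  or coordinates: connectivity is the only input.
- Closed-form counts stop at order 4; higher orders are available only
  through the line-graph route.
- Cycle counting beyond triangles is out of scope.
- The brute-force oracle is limited to p ≤ 64 by design; it exists as an
  independent check, not as a production path.
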