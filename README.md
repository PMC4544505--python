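# linemol

Exhaustive enumeration and indexing of *n*-body bonded intramolecular
interactions from molecular connectivity alone, via iterated line graphs.

Simulation engines need, for every molecule, the complete lists of bonds,
bends (angles) and dihedrals with the atoms participating in each. Given
only a molecular graph *G* — atoms (or coarse-grained beads) as vertices,
covalent bonds as edges — `linemol` generates all of these lists
systematically, so that a user can attach force constants and functional
forms afterwards. This topology-first workflow suits coarse-grained
models, where atom typing is unavailable and interaction lists must come
from connectivity.

## The method

The line graph *L(G)* has one vertex per edge of *G*; two vertices are
adjacent iff the parent edges share an endpoint. Algebraically,
A(L(G)) = Zᵀ Z − 2 I, with Z the vertex–edge incidence matrix of *G*.
Iterating the transformation climbs the interaction hierarchy: vertices of
*L*ⁿ⁻¹(*G*) are exactly the *n*-body interactions of the molecule, so
N_n(G) = |V(Lⁿ⁻¹(G))|. Closed forms over the adjacency matrix A, degree
matrix D and signless Laplacian Q = A + D provide independent checksums:

- N₂ = ½ Tr D = q (bonds, handshaking lemma)
- N₃ = ½ uᵀD²u − N₂ = Σ_v C(deg v, 2) (bends)
- N_impr = ⅙ uᵀD³u − N₃ − N₂/3 (improper dihedrals)
- N_prop + 3 N_3cyc = ½ uᵀD A D u − 2N₃ − N₂
- N_3cyc = ⅙ Tr A³ (triangles)
- N₄ = N_prop + 3N_impr + 3N_3cyc = ½ uᵀD Q D u − 5N₃ − 2N₂

The levels of iterated line graphs assemble into a ν-partite DAG whose
level-(n+1) vertices each have exactly two parents. Backtracking a level-n
vertex to the atoms yields a sequence of 2ⁿ⁻¹ atomic indexes whose
multiplicity pattern classifies every 4-body term: two triples → proper
torsion; one quadruple → improper dihedral; three distinct labels
(3+3+2) → degenerate 3-cycle. Impropers and 3-cycles each occur as three
rotational variants, which deduplicate to one physical record.

The package also computes the limit class of the iteration (cycles
reproduce, the claw collapses to a triangle, paths shrink to nothing,
everything else is *prolific*) and the line index ξ(G) — the least m with
*L*ᵐ(*G*) nonplanar, which is ≤ 4 for prolific graphs and infinite
otherwise.

## Worked example

The packaged 12-bead coarse-grained taurocholate bile salt model:

```sh
linemol counts src/linemol/data/taurocholate.edges --oracle
```

```json
{
  "schema": "linemol/counts/1",
  "n1": 12,
  "n2": 12,
  "n3": 16,
  "n4": 34,
  "n_prop": 22,
  "n_impr": 4,
  "n_3cyc": 0,
  "checksums": {
    "handshake_n2_equals_q": true,
    "n4_signless_laplacian_form": true,
    "brute_force_oracle": true
  }
}
```

Twelve beads and twelve bonds carry 16 bends and 34 four-body terms: 22
proper torsions plus 4 impropers, each improper counted three times for
its rotational variants (34 = 22 + 3·4); the acyclic topology has no
triangles. `--oracle` confirms the closed forms against direct subgraph
enumeration. The line index,

```sh
linemol line-index src/linemol/data/taurocholate.edges
# 2
```

says the second iterated line graph is the first nonplanar one. Other
subcommands: `enumerate` (canonical interaction records as TSV/JSON),
`line-graph` (edge list of *L*ⁿ(*G*) with nested labels), `dag`
(DOT/GraphML/TSV export of the hierarchy), `fixture` (named and seeded
random test graphs). The same operations are available from Python:

```python
import linemol as lm
g = lm.load_example("methylcyclopropane")
lm.closed_form_counts(g).counts_dict()
# {'n1': 4, 'n2': 4, 'n3': 5, 'n4': 8, 'n_prop': 2, 'n_impr': 1, 'n_3cyc': 1}
```

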