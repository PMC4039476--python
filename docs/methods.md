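# Methods

## Problem and matching semantics

Given a graph G whose edges carry a type (a single letter, declared
directed or undirected) and a small connected pattern P on k nodes, the
task is to enumerate every *instance* of P in G: an injective mapping of
pattern nodes to graph nodes under which every present pattern edge is
realized by a graph edge of the same type and direction. Matching is
partial (non-induced): a `0` token is "don't care", so extra graph edges
among the mapped nodes are irrelevant. At most one edge per (unordered
node pair, type) exists and self-loops are excluded; input preprocessing
enforces both (duplicate lines and both orientations of an undirected edge
are deduplicated, self-loop lines skipped with a logged warning).

Two instances that differ only by an automorphism of P are the same
subgraph; the enumeration is *minimal* in that exactly one representative
per such orbit is exported.

## Pattern encoding

`tokens[p]` encodes node pair (i, j), pairs ordered column by column:
(1,2), (1,3), (2,3), (1,4), … For a directed type, upper case means i→j
and lower case j→i; case is ignored for undirected types. The lower-case
convention is a convention of this package (the encoding's source leaves
it to an external reference); it reproduces the standard usages `SsS`
(directed 3-cycle), `XxXXXX` (directed tetrahedron) and `xXxXxx` (the
asymmetric G4 graph).

## Node IDs and the total order

Graph node IDs are contiguous integers assigned in lexicographically
sorted label order. Any total order makes the symmetry-breaking
constraints valid; fixing it to sorted labels makes output reproducible
across file orderings. The *set* of instance node-sets is invariant under
relabelling; the representative chosen per orbit is not, and the test
suite checks exactly that split.

## Symmetry analysis

The pattern is first refined into an equitable partition: every node in a
cell has the same number of present edges, per (type, direction role),
into every cell. Cells split by signature until stable; sub-cells replace
their parent in place, ordered by sorted signature (sub-cell signatures
are necessarily distinct, so this order is unambiguous; the smallest
member breaks any residual tie for determinism — the split ordering is a
design choice of this package, as is the canonical ordering of the final
cells by signature then smallest member).

Automorphisms are found by depth-first search over ordered partition
pairs (OPPs). Both partitions start equal. At each level the
lowest-indexed node in a non-singleton top cell is *coupled* — isolated in
a new singleton cell — to each member of the corresponding bottom cell in
increasing index, after which both partitions are independently re-refined.
A branch is pruned when the partitions stop corresponding: different cell
counts, a corresponding-cell size mismatch (stricter than cell-count
pruning alone, but sound — no bijection can respect unequal cells), or
differing cell signatures. A fully discrete OPP induces a permutation; it
is explicitly verified to preserve every present edge before being
recorded (a cheap backstop, k is small) and merges the global node-orbit
partition (union-find; merges are never undone on backtrack).

Orbit pruning: at each branch point, a bottom candidate is skipped if its
current orbit cell already contains a previously tried candidate — any
permutation it could lead to is a product of known ones. The search with
pruning disabled yields the same group and constraints (a tested
property), only with redundant work.

The first leaf reached is the identity. While backtracking along the
identity-prefix path (every earlier coupling mapped a node to itself),
when all couplings of node p are exhausted, the current orbit cell of p is
exactly the coset-representative set D_p: the nodes p can be mapped to
while all earlier nodes stay fixed. The stabiliser-chain subgroups behind
this reading are never generated — only the D_p are taken. Nodes a
refinement step forces into singletons get no D_p (they can only map to
themselves). Each q ∈ D_p \ {p} becomes the order constraint
m(p) < m(q) on mapped graph-node IDs. The constraint set is acyclic by
construction (checked); jointly the constraints select exactly one
representative per match orbit, verified exhaustively in the tests.

## Enumeration engine

Per pattern node the engine holds a collection of sorted candidate lists
awaiting intersection. Initially these are the type-membership lists, one
per required edge role. The first node to map is the one whose smallest
list is shortest; its candidates are the full intersection of its initial
lists, computed by a linear sweep (the lists are large at this point).
When a graph node v is mapped, the appropriately typed and directed
adjacency list of v is pushed onto every unmapped pattern neighbour
(direction is part of the type: a pattern edge q→p whose p end is mapped
to v pushes v's in-neighbour list onto q); lists are popped on backtrack,
restoring state exactly.

Node selection thereafter picks the unmapped node with the smallest held
list (an upper bound on its intersection), ties broken by lowest pattern
index; once a node holds at least one neighbour list its initial lists
drop out of both the estimate and the intersection — they only certify
edge presence, which the neighbour lists enforce anyway. The accepted
consequence is that a few candidates lacking some required edge type are
visited and pruned later. Candidates are computed by binary-searching the
constraint-bounded ID range (exclusive bounds from mapped constraint
partners; unmapped partners impose nothing) in the smallest list and
testing each member against the other lists by binary search; graph nodes
already used are excluded (injectivity). An optional look-ahead flag
abandons a branch as soon as a pushed neighbour list is empty; output is
unchanged, only traversal size. A hash-set mirror of the sorted lists
would shave intersection time further at roughly double the memory; it is
deliberately not kept.

Tie-breaks (lowest pattern index; candidates in increasing graph ID) make
two runs on the same input byte-identical.

## Synthetic data and oracles

The random generator draws, per edge type, each unordered node pair
independently with the configured density (an Erdős–Rényi G(n, p) per
type); directed types orient each realized edge uniformly. All randomness
flows from one integer seed; the same seed reproduces the same graph. The
randomized validation trials use n between 10 and 25 nodes, per-type
densities drawn from [0.10, 0.35], and one undirected plus one directed
type (plus a directed-only variant), which at these sizes gives the full
mix of zero, few and many matches per pattern while keeping exhaustive
enumeration cheap; 100 such trials run against six patterns covering
undirected, directed, multi-edge-type, don't-care and asymmetric cases.
What the generator does not emulate: degree heterogeneity, clustering and
degree correlations of real interaction networks. Passing trials
demonstrate correctness of the enumeration on arbitrary typed graphs, not
performance characteristics on scale-free data.

The brute-force oracles share no machinery with the engine: matches are
found by assigning pattern nodes in fixed index order over all graph
nodes, checking each required edge directly against the edge set;
automorphisms are the matches of a pattern in itself viewed as a graph (an
injective self-map sending present edges to present edges is a bijection
on a finite edge set, hence an automorphism). Guards keep brute force to
k ≤ 6 or n ≤ 12 (k ≤ 12 for automorphisms). Orbits of matches under
post-composition with automorphisms give the reference grouping the
matcher is checked against.

## Problem sizes and numerical choices

The bundled validation works at desk scale: patterns up to 10 nodes
(Petersen graph, 10-clique), graphs up to a few dozen nodes, where
exhaustive cross-checks are exact. There are no floating-point quantities
anywhere in the method; all comparisons are on integers, so no tolerances
apply. Degenerate inputs behave as follows: an empty edge file yields an
empty graph; a pattern type with no edges in the graph yields zero
instances (not an error); a pattern letter absent from the graph's
registry, or with mismatched directedness, is a configuration error.

## Known limitations

* Induced-subgraph (graphlet) semantics are out of scope; `0` is always
  "don't care".
* Only the pattern's symmetry is analysed, not the host graph's.
* Node and edge attributes beyond the type letter, parallel edges,
  weights and streaming graphs are unsupported.
* Single-pattern queries only; no multi-pattern sharing of search state.
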