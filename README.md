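# symmatch

Exact enumeration of small typed subgraph patterns ("composite network
motifs") in large networks, with automatic symmetry breaking so that each
instance is exported exactly once.

Biological interaction networks mix several edge types — physical, genetic
and signalling interactions between proteins, say — some directed, some
not. Counting how often a small pattern of such edges occurs is the
enumeration step behind every network-motif analysis, and the same
machinery applies to social and computer networks. The catch is pattern
symmetry: a triangle match can be written down in 3! = 6 orders, and a
naive search finds all six. `symmatch` detects the pattern's automorphism
group Aut(P) up front and converts it into node-ID order constraints that
admit exactly one representative per symmetry orbit, so the search never
even visits the permuted duplicates.

## Method in brief

A pattern P on k nodes is given as a token string of length k(k−1)/2: the
first token is the node pair (1,2), the next two are (1,3) and (2,3), and
so on. An upper-case letter on a directed type is the edge i→j, lower-case
the reversed edge j→i; `0` means "don't care" (partial, non-induced
matching). So `GGG` is a triangle, `XX00XX` a 4-ring, `SsS` a directed
3-cycle.

* **Symmetry detection.** Pattern nodes are grouped into an equitable
  partition (equal per-type, per-direction edge counts into every cell) and
  a depth-first search over *ordered partition pairs* couples the lowest
  unmapped node to each candidate in the corresponding cell, re-refining
  both partitions after every coupling. Discrete leaves yield
  automorphisms; orbit pruning skips couplings that can only rediscover
  known ones. Backtracking along the identity path reads off the coset
  representative sets D_p of the (never materialised) stabiliser chain, and
  each q ∈ D_p \ {p} becomes a constraint m(p) < m(q) on the IDs of the
  graph nodes mapped to p and q.
* **Enumeration.** An index-based backtracking search keeps, per pattern
  node, a collection of sorted candidate lists (type-membership lists at
  first, neighbour lists of mapped nodes thereafter), always expands the
  node whose smallest list is shortest, and intersects lists only within
  the ID range the constraints allow, located by binary search.

Exactly one member of each orbit of the match set under Aut(P) satisfies
the constraints, so the output is minimal: for the 10-node clique pattern
on a 10-node complete graph, 1 instance is exported instead of
10! = 3,628,800.

## Worked example

Enumerate triangles in the complete graph K4 (edge file `k4.txt` with one
`u v` line per edge, type X undirected):

```
$ symmatch --type X:u:k4.txt --pattern XXX -v
INFO loaded 4 nodes, 6 edges
INFO 2 generators, 3 symmetry-breaking constraints
INFO 4 instance(s) in 0.001 s
n0	n1	n2
n0	n1	n3
n0	n2	n3
n1	n2	n3
```

K4 contains 4·3·2 = 24 ordered triangle matches; the triangle's
automorphism group has order 6, and 24/6 = 4 orbit representatives are
printed — one line per instance, one column per pattern node, labels in
increasing ID order because the constraints force m(1) < m(2) < m(3).
Inspect a pattern's symmetry without searching:

```
$ symmatch --explain-symmetry --pattern XX00XX
pattern: XX00XX (4 nodes, 4 edges)
automorphism group order: 8
generators (2):
  (2 3)
  (1 2)(3 4)
node orbits: {1,2,3,4}
symmetry-breaking constraints (4):
  m(1) < m(2)
  m(1) < m(3)
  m(1) < m(4)
  m(2) < m(3)
```

The 4-ring's dihedral group (order 8) collapses to four order constraints;
of the 8 ways to traverse any 4-cycle, exactly one satisfies them.

The same functionality is available as a library
(`symmatch.load_typed_graph`, `parse_pattern`, `analyse_symmetry`,
`find_subgraph_instances`), plus seeded random typed-graph generators and
independent brute-force oracles under `symmatch` for validation work.

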