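"""Exact enumeration of small typed subgraph patterns in large networks.

Biological interaction networks mix several kinds of edges (physical,
genetic, signalling, ...), some directed and some not.  A *composite
network motif* is a small pattern over such typed edges, and counting its
occurrences is the enumeration step of every motif-significance pipeline.
The search here is index based: per-type sorted adjacency lists are
intersected while a backtracking search extends an injective mapping from
pattern nodes to graph nodes, always expanding the pattern node whose
candidate set is estimated to be smallest.

What makes the enumeration *minimal* is symmetry breaking.  The pattern's
automorphism group is detected automatically by an ordered-partition-pair
(OPP) search with equitable-partition refinement and orbit pruning; the
coset-representative sets read off the identity path of that search are
converted into node-ID order constraints.  A match and every other match
obtained from it by permuting pattern nodes with an automorphism form one
orbit, and the constraints admit exactly one representative per orbit, so
each instance is exported exactly once.

The module is laid out in the order the method runs:

1. typed graphs and edge-list I/O,
2. token-string pattern parsing,
3. pattern symmetry analysis (partitions, OPP search, constraints),
4. the enumeration engine,
5. independent brute-force oracles and synthetic graph generators
   (test support, but first-class code).
"""

from __future__ import annotations

import itertools
import logging
import random
from bisect import bisect_left, bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

logger = logging.getLogger("symmatch")

__all__ = [
    "OUT", "IN", "INCIDENT",
    "SymmatchError", "ConfigurationError", "PatternFormatError", "ValidationError",
    "EdgeType", "make_registry",
    "TypedGraph", "load_typed_graph", "write_edge_lists",
    "PatternEdge", "PatternGraph", "parse_pattern", "pattern_to_tokens", "tokens_from_edges",
    "Partition", "OPP", "initial_partition", "couple", "refine_opp",
    "SymmetryResult", "analyse_symmetry", "generate_constraints", "group_order",
    "permutation_cycles", "symmetry_report",
    "CandidateState", "PartialMapping", "select_next_node", "bounded_candidates",
    "find_subgraph_instances", "count_subgraph_instances", "instances_to_tsv",
    "GeneratorConfig", "random_typed_graph",
    "iter_brute_force_matches", "brute_force_matches", "brute_force_automorphisms",
    "orbit_partition_of_matches", "pattern_as_graph", "named_fixture", "PETERSEN_EDGES",
]

# Roles of a node with respect to an incident edge.  A directed edge type
# distinguishes the out and in endpoint; an undirected type has a single
# incident role.
OUT = "out"
IN = "in"
INCIDENT = "incident"


class SymmatchError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(SymmatchError):
    """An edge-type registry and the data given for it disagree."""


class PatternFormatError(SymmatchError):
    """A token string is not a well-formed pattern encoding."""


class ValidationError(SymmatchError):
    """Structurally valid input that violates a semantic requirement."""


# ---------------------------------------------------------------------------
# Edge types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeType:
    """One edge type: a single letter plus a directedness flag.

    The letter identifies the type case-insensitively; it is stored in
    upper case.  In token strings, case encodes direction for directed
    types (see :func:`parse_pattern`).
    """

    letter: str
    directed: bool

    def __post_init__(self) -> None:
        if len(self.letter) != 1 or not self.letter.isalpha():
            raise ConfigurationError(
                f"edge type letter must be a single alphabetic character, got {self.letter!r}")
        object.__setattr__(self, "letter", self.letter.upper())

    @property
    def roles(self) -> Tuple[str, ...]:
        return (OUT, IN) if self.directed else (INCIDENT,)


def make_registry(types: Iterable[Tuple[str, bool]]) -> Dict[str, EdgeType]:
    """Build a letter -> :class:`EdgeType` registry, rejecting duplicates."""
    registry: Dict[str, EdgeType] = {}
    for letter, directed in types:
        et = EdgeType(letter, directed)
        if et.letter in registry:
            raise ConfigurationError(f"duplicate edge type letter {et.letter!r}")
        registry[et.letter] = et
    return registry


# ---------------------------------------------------------------------------
# Typed graphs
# ---------------------------------------------------------------------------

class TypedGraph:
    """A node-labelled graph with typed edges and sorted per-type indexes.

    Node IDs are contiguous integers ``0..n-1`` assigned in sorted label
    order, so the same node set always receives the same IDs regardless of
    file or construction order.  The IDs define the global total order the
    symmetry-breaking constraints compare.

    Edges are stored once per (unordered pair, type); undirected edges are
    canonicalised to ``(min_id, max_id)``.  Self-loops and parallel edges
    of the same type are not representable.
    """

    def __init__(self, registry: Mapping[str, EdgeType],
                 node_labels: Iterable[str],
                 edges: Iterable[Tuple[int, int, str]]):
        self.registry = dict(registry)
        self.node_labels: Tuple[str, ...] = tuple(node_labels)
        if list(self.node_labels) != sorted(set(self.node_labels)):
            raise ValidationError("node labels must be unique and sorted")
        self._id_of = {label: i for i, label in enumerate(self.node_labels)}
        self.edges: FrozenSet[Tuple[int, int, str]] = frozenset(
            self._canonical(u, v, t) for (u, v, t) in edges)
        for (u, v, t) in self.edges:
            if u == v:
                raise ValidationError(f"self-loop on node {self.node_labels[u]!r}")
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise ValidationError("edge endpoint outside node range")
        self._build_indexes()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edge_list(cls, registry: Mapping[str, EdgeType],
                       labelled_edges: Iterable[Tuple[str, str, str]],
                       extra_nodes: Iterable[str] = ()) -> "TypedGraph":
        """Build a graph from ``(u_label, v_label, type_letter)`` triplets."""
        labelled_edges = list(labelled_edges)
        labels = set(extra_nodes)
        for u, v, t in labelled_edges:
            if t.upper() not in registry:
                raise ConfigurationError(f"edge type {t!r} not registered")
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            labels.add(u)
            labels.add(v)
        order = sorted(labels)
        id_of = {label: i for i, label in enumerate(order)}
        return cls(registry, order,
                   [(id_of[u], id_of[v], t.upper()) for u, v, t in labelled_edges])

    def _canonical(self, u: int, v: int, t: str) -> Tuple[int, int, str]:
        t = t.upper()
        if t not in self.registry:
            raise ConfigurationError(f"edge type {t!r} not registered")
        if not self.registry[t].directed and u > v:
            u, v = v, u
        return (u, v, t)

    def _build_indexes(self) -> None:
        adj: Dict[Tuple[str, str], Dict[int, List[int]]] = defaultdict(lambda: defaultdict(list))
        for (u, v, t) in self.edges:
            if self.registry[t].directed:
                adj[(t, OUT)][u].append(v)
                adj[(t, IN)][v].append(u)
            else:
                adj[(t, INCIDENT)][u].append(v)
                adj[(t, INCIDENT)][v].append(u)
        self._adj: Dict[Tuple[str, str], Dict[int, Tuple[int, ...]]] = {}
        self._members: Dict[Tuple[str, str], Tuple[int, ...]] = {}
        for t, et in self.registry.items():
            for role in et.roles:
                per_node = {u: tuple(sorted(nbrs)) for u, nbrs in adj[(t, role)].items()}
                self._adj[(t, role)] = per_node
                self._members[(t, role)] = tuple(sorted(per_node))

    # -- queries -----------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def id_of(self, label: str) -> int:
        return self._id_of[label]

    def label_of(self, node: int) -> str:
        return self.node_labels[node]

    def _check_role(self, letter: str, role: str) -> None:
        letter = letter.upper()
        if letter not in self.registry:
            raise ConfigurationError(f"edge type {letter!r} not registered")
        if role not in self.registry[letter].roles:
            kind = "directed" if self.registry[letter].directed else "undirected"
            raise ValueError(f"role {role!r} invalid for {kind} type {letter!r}")

    def neighbours(self, node: int, letter: str, role: str) -> Tuple[int, ...]:
        """Sorted IDs of neighbours of ``node`` through ``letter`` edges in ``role``."""
        self._check_role(letter, role)
        if not (0 <= node < self.n):
            raise ValueError(f"node ID {node} out of range")
        return self._adj[(letter.upper(), role)].get(node, ())

    def members(self, letter: str, role: str) -> Tuple[int, ...]:
        """Sorted IDs of all nodes with at least one ``letter`` edge in ``role``."""
        self._check_role(letter, role)
        return self._members[(letter.upper(), role)]

    def has_edge(self, u: int, v: int, letter: str) -> bool:
        letter = letter.upper()
        if letter not in self.registry:
            raise ConfigurationError(f"edge type {letter!r} not registered")
        if not self.registry[letter].directed and u > v:
            u, v = v, u
        return (u, v, letter) in self.edges


def load_typed_graph(specs: Sequence[Tuple[str, bool, str]]) -> TypedGraph:
    """Load a :class:`TypedGraph` from per-type two-column edge-list files.

    ``specs`` is a list of ``(type_letter, directed, path)``.  Each
    non-comment line of a file names one edge ``u v`` (extra whitespace
    separated tokens are ignored).  Duplicate lines and, for undirected
    types, both orientations of the same edge collapse to a single edge.
    Self-loop lines are skipped with a logged warning.
    """
    registry = make_registry([(letter, directed) for letter, directed, _ in specs])
    labelled: List[Tuple[str, str, str]] = []
    skipped_self_loops = 0
    for letter, _directed, path in specs:
        letter = letter.upper()
        with open(path, "r", encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValidationError(
                        f"{path}:{lineno}: expected at least two columns, got {line!r}")
                u, v = parts[0], parts[1]
                if u == v:
                    skipped_self_loops += 1
                    logger.warning("%s:%d: skipping self-loop on %r", path, lineno, u)
                    continue
                labelled.append((u, v, letter))
    if skipped_self_loops:
        logger.warning("skipped %d self-loop line(s) in total", skipped_self_loops)
    return TypedGraph.from_edge_list(registry, labelled)


def write_edge_lists(graph: TypedGraph, paths: Mapping[str, str]) -> None:
    """Write the graph back to one two-column edge-list file per type.

    Each edge is written once, endpoints as labels, in sorted ID order;
    reloading with :func:`load_typed_graph` reproduces the graph exactly.
    """
    by_type: Dict[str, List[Tuple[int, int]]] = {t: [] for t in graph.registry}
    for (u, v, t) in graph.edges:
        by_type[t].append((u, v))
    for t, path in paths.items():
        t = t.upper()
        with open(path, "w", encoding="utf-8") as handle:
            for u, v in sorted(by_type.get(t, [])):
                handle.write(f"{graph.label_of(u)} {graph.label_of(v)}\n")


# ---------------------------------------------------------------------------
# Patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternEdge:
    """A present pattern edge between 0-based pattern nodes ``i < j``.

    ``direction`` is ``None`` for undirected types, otherwise ``(src, dst)``
    as an ordered pair drawn from ``{i, j}``.
    """

    i: int
    j: int
    letter: str
    direction: Optional[Tuple[int, int]]

    def role_from(self, node: int) -> str:
        if self.direction is None:
            return INCIDENT
        return OUT if self.direction[0] == node else IN


@dataclass(frozen=True)
class PatternGraph:
    """A small pattern parsed from a token string.

    ``tokens`` has triangular length k(k-1)/2; token position ``p`` encodes
    the node pair ``(i, j)`` column by column: the first token is the
    (1,2) pair, the next two are (1,3) and (2,3), and so on.  A ``'0'``
    token is "don't care": the corresponding graph edge may be present or
    absent and imposes no constraint (partial, non-induced matching).
    """

    k: int
    tokens: str
    edges: Tuple[PatternEdge, ...]
    registry: Mapping[str, EdgeType] = field(hash=False, compare=False)

    def incident(self, node: int) -> Tuple[Tuple[int, str, str], ...]:
        """``(other, letter, role_from_node)`` for each present edge at ``node``."""
        out = []
        for e in self.edges:
            if node in (e.i, e.j):
                other = e.j if node == e.i else e.i
                out.append((other, e.letter, e.role_from(node)))
        return tuple(out)

    def realized(self, e: PatternEdge, mapping: Sequence[int]) -> Tuple[int, int, str]:
        """The graph-edge triplet a mapping must realize for pattern edge ``e``."""
        if e.direction is None:
            return (mapping[e.i], mapping[e.j], e.letter)
        src, dst = e.direction
        return (mapping[src], mapping[dst], e.letter)


def _triangular_k(length: int) -> int:
    k = 2
    while k * (k - 1) // 2 < length:
        k += 1
    if length == 0 or k * (k - 1) // 2 != length:
        raise PatternFormatError(
            f"token string length {length} is not a triangular number k(k-1)/2")
    return k


def _pair_of_position(p: int) -> Tuple[int, int]:
    # positions fill column j = 1, 2, ... (0-based), rows i = 0..j-1
    j = 1
    while j * (j + 1) // 2 <= p:
        j += 1
    i = p - j * (j - 1) // 2
    return i, j


def parse_pattern(tokens: str, registry: Mapping[str, EdgeType]) -> PatternGraph:
    """Parse a token string into a :class:`PatternGraph`.

    For a directed type, an upper-case token at pair ``(i, j)`` is the edge
    ``i -> j`` and a lower-case token the reversed edge ``j -> i``; case is
    ignored for undirected types.  The pattern must be connected over its
    present edges.
    """
    k = _triangular_k(len(tokens))
    edges: List[PatternEdge] = []
    for p, ch in enumerate(tokens):
        if ch == "0":
            continue
        letter = ch.upper()
        if letter not in registry:
            raise ConfigurationError(f"pattern token {ch!r} is not a registered edge type")
        i, j = _pair_of_position(p)
        et = registry[letter]
        if et.directed:
            direction = (i, j) if ch.isupper() else (j, i)
        else:
            direction = None
        edges.append(PatternEdge(i, j, letter, direction))
    # connectivity over present edges
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        parent[find(e.i)] = find(e.j)
    if len({find(x) for x in range(k)}) != 1:
        raise ValidationError(f"pattern {tokens!r} is not connected over its present edges")
    return PatternGraph(k, tokens, tuple(edges), dict(registry))


def tokens_from_edges(k: int, edges: Iterable[Tuple[int, int, str, Optional[Tuple[int, int]]]]) -> str:
    """Regenerate a token string from ``(i, j, letter, direction)`` tuples."""
    out = ["0"] * (k * (k - 1) // 2)
    for i, j, letter, direction in edges:
        if i > j:
            i, j = j, i
        if not 0 <= i < j < k:
            raise ValueError(f"invalid pattern pair ({i}, {j}) for k={k}")
        pos = j * (j - 1) // 2 + i
        if direction is not None and direction == (j, i):
            out[pos] = letter.lower()
        else:
            out[pos] = letter.upper()
    return "".join(out)


def pattern_to_tokens(pattern: PatternGraph) -> str:
    """Inverse of :func:`parse_pattern` up to case on undirected types."""
    return tokens_from_edges(
        pattern.k, [(e.i, e.j, e.letter, e.direction) for e in pattern.edges])


# ---------------------------------------------------------------------------
# Symmetry analysis
# ---------------------------------------------------------------------------
#
# The pattern's automorphism group is found by a depth-first search over
# ordered partition pairs (OPPs).  Both partitions start from the same
# equitable partition of the pattern.  A *coupling* maps the lowest
# unmapped top node onto each member of the corresponding bottom cell in
# turn; refinement restores equitability on both sides independently and
# prunes when the two sides stop corresponding.  A fully discrete OPP reads
# off a permutation.  The first leaf is the identity; while backtracking
# along that identity path, the orbit cell of the node whose couplings were
# just exhausted is its coset-representative set D_p, and each q in
# D_p \ {p} yields the order constraint m(p) < m(q).

Partition = Tuple[Tuple[int, ...], ...]
OPP = Tuple[Partition, Partition]
Permutation = Tuple[int, ...]


def _signature(node: int, cell_index: Mapping[int, int], pattern: PatternGraph):
    counts: Counter = Counter()
    for other, letter, role in pattern.incident(node):
        counts[(cell_index[other], letter, role)] += 1
    return tuple(sorted(counts.items()))


def _refine_partition(cells: Partition, pattern: PatternGraph) -> Partition:
    """Split cells by edge-count signature until equitable (fixpoint).

    Sub-cells of a split replace their parent in place, ordered by sorted
    signature; signatures of sub-cells are necessarily distinct, so the
    order is unambiguous (ties broken by smallest member for determinism).
    """
    while True:
        cell_index = {v: ci for ci, cell in enumerate(cells) for v in cell}
        new_cells: List[Tuple[int, ...]] = []
        changed = False
        for cell in cells:
            if len(cell) == 1:
                new_cells.append(cell)
                continue
            groups: Dict[tuple, List[int]] = defaultdict(list)
            for v in cell:
                groups[_signature(v, cell_index, pattern)].append(v)
            if len(groups) == 1:
                new_cells.append(cell)
            else:
                changed = True
                for sig in sorted(groups, key=lambda s: (s, min(groups[s]))):
                    new_cells.append(tuple(sorted(groups[sig])))
        cells = tuple(new_cells)
        if not changed:
            return cells


def _cell_signatures(cells: Partition, pattern: PatternGraph) -> List[tuple]:
    cell_index = {v: ci for ci, cell in enumerate(cells) for v in cell}
    # equitable at fixpoint: any member is representative of its cell
    return [_signature(cell[0], cell_index, pattern) for cell in cells]


def initial_partition(pattern: PatternGraph) -> Partition:
    """Equitable partition of the pattern nodes, canonically ordered.

    Every node in a cell has the same count of present edges, per type and
    direction role, to every cell.  Cells are ordered by their signature,
    ties by smallest member.
    """
    cells = _refine_partition((tuple(range(pattern.k)),), pattern)
    sigs = _cell_signatures(cells, pattern)
    order = sorted(range(len(cells)), key=lambda ci: (sigs[ci], cells[ci][0]))
    return tuple(cells[ci] for ci in order)


def couple(opp: OPP, top_node: int, bottom_node: int) -> OPP:
    """Isolate ``top_node`` and ``bottom_node`` in new corresponding singleton cells."""
    top, bottom = opp
    ci = next(i for i, cell in enumerate(top) if top_node in cell)
    if bottom_node not in bottom[ci]:
        raise ValueError(
            f"bottom node {bottom_node} not in the cell corresponding to {top_node}")

    def split(cells: Partition, node: int) -> Partition:
        cell = cells[ci]
        rest = tuple(v for v in cell if v != node)
        new = ((node,),) + ((rest,) if rest else ())
        return cells[:ci] + new + cells[ci + 1:]

    return (split(top, top_node), split(bottom, bottom_node))


def refine_opp(opp: OPP, pattern: PatternGraph) -> Optional[OPP]:
    """Refine both partitions independently; ``None`` signals a pruned branch.

    The branch is pruned when the refined partitions stop corresponding:
    different cell counts, a corresponding-cell size mismatch, or different
    cell signatures.  Size-mismatch pruning is stricter than cell-count
    pruning alone but sound — no node bijection can respect cells of
    unequal size.
    """
    top = _refine_partition(opp[0], pattern)
    bottom = _refine_partition(opp[1], pattern)
    if len(top) != len(bottom):
        return None
    for tc, bc in zip(top, bottom):
        if len(tc) != len(bc):
            return None
    if _cell_signatures(top, pattern) != _cell_signatures(bottom, pattern):
        return None
    return (top, bottom)


def _is_automorphism(perm: Permutation, pattern: PatternGraph) -> bool:
    present = set()
    for e in pattern.edges:
        if e.direction is None:
            present.add((frozenset((e.i, e.j)), e.letter))
        else:
            present.add((e.direction, e.letter))
    for e in pattern.edges:
        if e.direction is None:
            key = (frozenset((perm[e.i], perm[e.j])), e.letter)
        else:
            key = ((perm[e.direction[0]], perm[e.direction[1]]), e.letter)
        if key not in present:
            return False
    return True


@dataclass
class SymmetryResult:
    """Outcome of the pattern symmetry analysis.

    ``generators`` generate Aut(pattern); ``orbits`` is the node-orbit
    partition under that group; ``coset_reps[p]`` is D_p, the set of nodes
    p can be mapped to while all earlier coupled nodes stay fixed (only
    defined for nodes coupled on the identity path — nodes a refinement
    step fixes get no D_p).  ``constraints`` is the set of ``(p, q)`` pairs
    meaning "the graph ID mapped to p must be smaller than the one mapped
    to q"; jointly they admit exactly one representative per match orbit.
    The stabiliser-chain subgroups behind D_p's meaning are never
    materialised — only their coset representatives are read off.
    """

    generators: List[Permutation]
    orbits: Tuple[Tuple[int, ...], ...]
    coset_reps: Dict[int, FrozenSet[int]]
    constraints: FrozenSet[Tuple[int, int]]


def generate_constraints(coset_reps: Mapping[int, FrozenSet[int]]) -> FrozenSet[Tuple[int, int]]:
    """One constraint ``(p, q)`` per ``q`` in ``D_p \\ {p}``; must be acyclic."""
    constraints = frozenset(
        (p, q) for p, reps in coset_reps.items() for q in reps if q != p)
    graph: Dict[int, List[int]] = defaultdict(list)
    for p, q in constraints:
        graph[q].append(p)
    try:
        tuple(TopologicalSorter(graph).static_order())
    except CycleError as err:  # pragma: no cover - internal invariant
        raise RuntimeError(f"cyclic symmetry-breaking constraints: {constraints}") from err
    return constraints


def analyse_symmetry(pattern: PatternGraph, *, orbit_pruning: bool = True) -> SymmetryResult:
    """Detect Aut(pattern) and derive symmetry-breaking order constraints.

    Depth-first OPP search: at each level the lowest-indexed unmapped node
    is coupled to every candidate of the corresponding bottom cell in
    increasing index, the OPP is refined, and the search recurses.  Each
    discrete leaf whose induced permutation preserves all present edges is
    recorded and merges node orbits.  Orbit pruning skips a bottom
    candidate whose current orbit already contains a candidate tried at the
    same branch point (merges are never undone — the orbit partition only
    grows).  ``orbit_pruning=False`` explores the full tree and must yield
    the same group and constraints, possibly with redundant generators.
    """
    k = pattern.k
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            if rb < ra:
                ra, rb = rb, ra
            parent[rb] = ra

    identity = tuple(range(k))
    generators: List[Permutation] = []
    coset_reps: Dict[int, FrozenSet[int]] = {}

    def process(opp: OPP, identity_prefix: bool) -> None:
        top, bottom = opp
        if all(len(cell) == 1 for cell in top):
            perm = [0] * k
            for tc, bc in zip(top, bottom):
                perm[tc[0]] = bc[0]
            p = tuple(perm)
            if p != identity and _is_automorphism(p, pattern):
                generators.append(p)
                for x in range(k):
                    union(x, p[x])
            return
        node = min(v for cell in top if len(cell) > 1 for v in cell)
        ci = next(i for i, cell in enumerate(top) if node in cell)
        tried: List[int] = []
        for w in sorted(bottom[ci]):
            if orbit_pruning and any(find(w) == find(t) for t in tried):
                continue
            tried.append(w)
            child = refine_opp(couple(opp, node, w), pattern)
            if child is not None:
                process(child, identity_prefix and w == node)
        if identity_prefix:
            # All couplings of `node` with earlier nodes fixed are exhausted:
            # its orbit cell now is exactly the coset-representative set D_p.
            coset_reps[node] = frozenset(x for x in range(k) if find(x) == find(node))

    start = initial_partition(pattern)
    process((start, start), True)

    cells: Dict[int, List[int]] = defaultdict(list)
    for x in range(k):
        cells[find(x)].append(x)
    orbits = tuple(tuple(sorted(cell)) for _, cell in sorted(cells.items()))
    constraints = generate_constraints(coset_reps)
    return SymmetryResult(generators, orbits, coset_reps, constraints)


def group_order(generators: Sequence[Permutation], k: Optional[int] = None) -> int:
    """Order of the permutation group generated by ``generators`` (closure)."""
    if not generators:
        return 1
    if k is None:
        k = len(generators[0])
    identity = tuple(range(k))
    seen = {identity}
    frontier = [identity]
    while frontier:
        nxt = []
        for g in frontier:
            for h in generators:
                composed = tuple(h[g[i]] for i in range(k))
                if composed not in seen:
                    seen.add(composed)
                    nxt.append(composed)
        frontier = nxt
    return len(seen)


def permutation_cycles(perm: Permutation) -> str:
    """Cycle notation with 1-based node numbers, e.g. ``(1 2)(3 4)``."""
    seen = set()
    parts = []
    for start in range(len(perm)):
        if start in seen or perm[start] == start:
            seen.add(start)
            continue
        cycle = [start]
        seen.add(start)
        x = perm[start]
        while x != start:
            cycle.append(x)
            seen.add(x)
            x = perm[x]
        parts.append("(" + " ".join(str(v + 1) for v in cycle) + ")")
    return "".join(parts) or "()"


def symmetry_report(result: SymmetryResult, pattern: PatternGraph) -> str:
    """Plain-text account of a pattern's symmetry (1-based node numbers)."""
    lines = [f"pattern: {pattern.tokens} ({pattern.k} nodes, {len(pattern.edges)} edges)"]
    order = group_order(result.generators, pattern.k)
    lines.append(f"automorphism group order: {order}")
    lines.append(f"generators ({len(result.generators)}):")
    for g in result.generators:
        lines.append(f"  {permutation_cycles(g)}")
    lines.append("node orbits: " + " ".join(
        "{" + ",".join(str(v + 1) for v in cell) + "}" for cell in result.orbits))
    lines.append(f"symmetry-breaking constraints ({len(result.constraints)}):")
    for p, q in sorted(result.constraints):
        lines.append(f"  m({p + 1}) < m({q + 1})")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Enumeration engine
# ---------------------------------------------------------------------------

class PartialMapping:
    """Injective partial mapping pattern node -> graph node ID."""

    __slots__ = ("assigned", "used")

    def __init__(self, k: int):
        self.assigned: List[Optional[int]] = [None] * k
        self.used: set = set()

    def assign(self, p: int, v: int) -> None:
        self.assigned[p] = v
        self.used.add(v)

    def unassign(self, p: int) -> None:
        self.used.discard(self.assigned[p])
        self.assigned[p] = None


class CandidateState:
    """Per-pattern-node collections of sorted candidate lists.

    Each pattern node starts with its *initial* lists — the type-membership
    lists for each of its required edge roles.  When a neighbouring pattern
    node is mapped to graph node v, the matching adjacency list of v is
    pushed; popping on backtrack restores the state exactly.  Initial lists
    are used for the selection estimate and intersection only while a node
    holds no neighbour list: they are large and only certify edge presence,
    which the pushed neighbour lists enforce anyway.
    """

    def __init__(self, graph: TypedGraph, pattern: PatternGraph,
                 constraints: FrozenSet[Tuple[int, int]]):
        self.graph = graph
        self.pattern = pattern
        self.initial_lists: List[Tuple[Tuple[int, ...], ...]] = [
            tuple(graph.members(letter, role) for _, letter, role in pattern.incident(p))
            for p in range(pattern.k)
        ]
        self.neighbour_lists: List[List[Tuple[int, ...]]] = [[] for _ in range(pattern.k)]
        # m(q) < m(p) partners (lower bound) and m(p) < m(q) partners (upper bound)
        self.lower_partners: List[Tuple[int, ...]] = [
            tuple(q for q, pp in constraints if pp == p) for p in range(pattern.k)]
        self.upper_partners: List[Tuple[int, ...]] = [
            tuple(q for pp, q in constraints if pp == p) for p in range(pattern.k)]

    def active_lists(self, p: int) -> Sequence[Tuple[int, ...]]:
        return self.neighbour_lists[p] or self.initial_lists[p]

    def estimate(self, p: int) -> int:
        return min(len(lst) for lst in self.active_lists(p))


def select_next_node(state: CandidateState, unmapped: Iterable[int]) -> int:
    """Unmapped node with the smallest estimated candidate set.

    The estimate is the length of the node's smallest held list (an upper
    bound on the intersection size); initial type-membership lists count
    only while a node holds no neighbour list.  Ties break on the lowest
    pattern index.
    """
    return min(unmapped, key=lambda p: (state.estimate(p), p))


def _contains(sorted_list: Tuple[int, ...], v: int) -> bool:
    i = bisect_left(sorted_list, v)
    return i < len(sorted_list) and sorted_list[i] == v


def bounded_candidates(state: CandidateState, node: int,
                       mapping: PartialMapping) -> List[int]:
    """Sorted candidate IDs for ``node`` within its constraint bounds.

    Mapped constraint partners bound the allowed ID range (exclusively) on
    both sides; unmapped partners impose nothing.  The bounded range of the
    smallest held list is located by binary search and each member is
    tested against the other lists by binary search; graph nodes already
    used by the partial mapping are excluded.
    """
    lists = state.active_lists(node)
    lower = -1
    for q in state.lower_partners[node]:
        v = mapping.assigned[q]
        if v is not None and v > lower:
            lower = v
    upper = state.graph.n
    for q in state.upper_partners[node]:
        v = mapping.assigned[q]
        if v is not None and v < upper:
            upper = v
    if lower >= upper:
        return []
    smallest = min(lists, key=len)
    start = bisect_right(smallest, lower)
    end = bisect_left(smallest, upper)
    used = mapping.used
    out = []
    for v in smallest[start:end]:
        if v in used:
            continue
        if all(lst is smallest or _contains(lst, v) for lst in lists):
            out.append(v)
    return out


def _sweep_intersection(lists: Sequence[Tuple[int, ...]]) -> List[int]:
    """Intersection of sorted lists by a single linear sweep."""
    if not lists:
        return []
    lists = sorted(lists, key=len)
    result = list(lists[0])
    for other in lists[1:]:
        merged = []
        i = j = 0
        while i < len(result) and j < len(other):
            a, b = result[i], other[j]
            if a == b:
                merged.append(a)
                i += 1
                j += 1
            elif a < b:
                i += 1
            else:
                j += 1
        result = merged
        if not result:
            break
    return result


def _check_pattern_types(graph: TypedGraph, pattern: PatternGraph) -> None:
    for e in pattern.edges:
        et = graph.registry.get(e.letter)
        if et is None:
            raise ConfigurationError(
                f"pattern edge type {e.letter!r} not registered in the graph")
        if et.directed != (e.direction is not None):
            raise ConfigurationError(
                f"edge type {e.letter!r} directedness differs between pattern and graph")


def find_subgraph_instances(graph: TypedGraph, pattern: PatternGraph, *,
                            symmetry: Optional[SymmetryResult] = None,
                            lookahead: bool = False,
                            verify: bool = False) -> Iterator[Tuple[str, ...]]:
    """Enumerate one representative per symmetry orbit of each pattern instance.

    Yields tuples of graph node labels, one per pattern node in pattern
    order, in deterministic depth-first order.  The symmetry analysis runs
    once up front (or is supplied precomputed); its order constraints bound
    the candidate ID ranges during the search, so permuted duplicates of an
    instance are never visited.  ``lookahead`` additionally abandons a
    branch as soon as a pushed neighbour list is empty (same output,
    smaller traversal).  ``verify`` re-checks every emitted instance edge by
    edge and against every constraint (test support).
    """
    _check_pattern_types(graph, pattern)
    if symmetry is None:
        symmetry = analyse_symmetry(pattern)
    k = pattern.k
    state = CandidateState(graph, pattern, symmetry.constraints)
    mapping = PartialMapping(k)
    unmapped = set(range(k))

    first = min(range(k), key=lambda p: (state.estimate(p), p))
    # Initial candidates come from the full set of type-membership lists,
    # intersected with a linear sweep (they are large at this point).
    first_candidates = _sweep_intersection(state.initial_lists[first])

    def emit() -> Tuple[str, ...]:
        assigned = mapping.assigned
        if verify:
            for e in pattern.edges:
                u, v, t = pattern.realized(e, assigned)  # type: ignore[arg-type]
                if not graph.has_edge(u, v, t):
                    raise AssertionError(f"emitted instance misses edge {(u, v, t)}")
            for p, q in symmetry.constraints:
                if not assigned[p] < assigned[q]:  # type: ignore[operator]
                    raise AssertionError(f"constraint m({p})<m({q}) violated")
        return tuple(graph.label_of(v) for v in assigned)  # type: ignore[arg-type]

    def map_nodes(node: int, candidates: List[int]) -> Iterator[Tuple[str, ...]]:
        for v in candidates:
            mapping.assign(node, v)
            unmapped.discard(node)
            if not unmapped:
                yield emit()
            else:
                pushed = []
                dead = False
                for other, letter, role in pattern.incident(node):
                    if mapping.assigned[other] is None:
                        lst = graph.neighbours(v, letter, role)
                        state.neighbour_lists[other].append(lst)
                        pushed.append(other)
                        if not lst:
                            dead = True
                if not (lookahead and dead):
                    nxt = select_next_node(state, unmapped)
                    yield from map_nodes(nxt, bounded_candidates(state, nxt, mapping))
                for other in pushed:
                    state.neighbour_lists[other].pop()
            unmapped.add(node)
            mapping.unassign(node)

    yield from map_nodes(first, first_candidates)


def count_subgraph_instances(graph: TypedGraph, pattern: PatternGraph, **kwargs) -> int:
    return sum(1 for _ in find_subgraph_instances(graph, pattern, **kwargs))


def instances_to_tsv(instances: Iterable[Tuple[str, ...]], *,
                     header: Optional[Sequence[str]] = None) -> str:
    """Render instances as TSV, one line per instance, columns in pattern order."""
    lines = []
    if header is not None:
        lines.append("\t".join(header))
    for record in instances:
        lines.append("\t".join(record))
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Brute-force oracles and synthetic graphs
# ---------------------------------------------------------------------------
#
# The oracles deliberately share no candidate machinery with the engine
# above: they check edges one by one against the graph's edge set while
# recursing over pattern nodes in fixed index order.  Their correctness is
# argued from first principles, which is what lets them vouch for the
# matcher in the property tests.

def _brute_guard(graph: TypedGraph, pattern: PatternGraph) -> None:
    if pattern.k > 6 and graph.n > 12:
        raise ValueError(
            f"brute force refused: pattern k={pattern.k} on n={graph.n} graph "
            "(guard: k <= 6 or n <= 12)")


def iter_brute_force_matches(graph: TypedGraph,
                             pattern: PatternGraph) -> Iterator[Tuple[int, ...]]:
    """All injective mappings realizing every present edge (IDs, fixed order).

    Pattern nodes are assigned in index order 0..k-1; a candidate is
    rejected as soon as an edge to an already-assigned node is missing.
    Don't-care pairs impose nothing.
    """
    _check_pattern_types(graph, pattern)
    _brute_guard(graph, pattern)
    k = pattern.k
    checks: List[List[Tuple[int, str, Optional[Tuple[int, int]]]]] = [[] for _ in range(k)]
    for e in pattern.edges:
        later, earlier = max(e.i, e.j), min(e.i, e.j)
        checks[later].append((earlier, e.letter, e.direction))
    assigned: List[int] = []

    def extend(p: int) -> Iterator[Tuple[int, ...]]:
        if p == k:
            yield tuple(assigned)
            return
        for v in range(graph.n):
            if v in assigned:
                continue
            ok = True
            for other, letter, direction in checks[p]:
                if direction is None:
                    u, w = assigned[other], v
                elif direction == (other, p) or direction == (p, other):
                    src, dst = direction
                    u = assigned[other] if src == other else v
                    w = v if dst == p else assigned[other]
                if not graph.has_edge(u, w, letter):
                    ok = False
                    break
            if ok:
                assigned.append(v)
                yield from extend(p + 1)
                assigned.pop()

    yield from extend(0)


def brute_force_matches(graph: TypedGraph, pattern: PatternGraph) -> List[Tuple[int, ...]]:
    return list(iter_brute_force_matches(graph, pattern))


def pattern_as_graph(pattern: PatternGraph) -> TypedGraph:
    """The pattern's present edges as a :class:`TypedGraph` on nodes ``p0..p{k-1}``."""
    labels = [f"p{i:02d}" for i in range(pattern.k)]
    edges = []
    for e in pattern.edges:
        if e.direction is None:
            edges.append((labels[e.i], labels[e.j], e.letter))
        else:
            edges.append((labels[e.direction[0]], labels[e.direction[1]], e.letter))
    return TypedGraph.from_edge_list(pattern.registry, edges, extra_nodes=labels)


def brute_force_automorphisms(pattern: PatternGraph) -> List[Permutation]:
    """All node permutations preserving every present edge, type and direction.

    Found by matching the pattern against itself viewed as a graph: an
    injective self-map sending every present edge to a present edge is a
    bijection on a finite edge set and hence an automorphism.
    """
    if pattern.k > 12:
        raise ValueError(f"brute force refused for k={pattern.k} > 12")
    return brute_force_matches(pattern_as_graph(pattern), pattern)


def orbit_partition_of_matches(matches: Sequence[Tuple[int, ...]],
                               automorphisms: Sequence[Permutation],
                               ) -> List[List[Tuple[int, ...]]]:
    """Group matches into orbits under post-composition with automorphisms.

    Two matches m and m' are in one orbit iff m' = m . pi for some
    automorphism pi.  Orbit sizes divide the group order (Lagrange).
    """
    index = {m: i for i, m in enumerate(matches)}
    remaining = set(range(len(matches)))
    orbits: List[List[Tuple[int, ...]]] = []
    while remaining:
        seed = min(remaining)
        orbit_ids = set()
        frontier = [matches[seed]]
        while frontier:
            m = frontier.pop()
            i = index[m]
            if i in orbit_ids:
                continue
            orbit_ids.add(i)
            for pi in automorphisms:
                composed = tuple(m[pi[j]] for j in range(len(m)))
                if composed in index and index[composed] not in orbit_ids:
                    frontier.append(composed)
        remaining -= orbit_ids
        orbits.append([matches[i] for i in sorted(orbit_ids)])
    return orbits


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the seeded random typed-graph generator.

    ``densities`` maps type letters to independent per-pair edge
    probabilities in [0, 1]; directed types orient each realized edge
    uniformly at random.  Identical seeds give identical graphs.
    """

    n: int
    densities: Mapping[str, float]
    registry: Mapping[str, EdgeType]
    seed: int

    def __post_init__(self) -> None:
        for letter, d in self.densities.items():
            if letter.upper() not in self.registry:
                raise ConfigurationError(f"density given for unregistered type {letter!r}")
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"density for {letter!r} outside [0, 1]: {d}")


def random_typed_graph(config: GeneratorConfig) -> TypedGraph:
    """Seeded Erdos-Renyi-style generator, independently per edge type."""
    rng = random.Random(config.seed)
    labels = [f"v{i:04d}" for i in range(config.n)]
    edges: List[Tuple[str, str, str]] = []
    for letter in sorted(config.densities):
        density = config.densities[letter]
        directed = config.registry[letter.upper()].directed
        for i in range(config.n):
            for j in range(i + 1, config.n):
                if rng.random() < density:
                    if directed and rng.random() < 0.5:
                        edges.append((labels[j], labels[i], letter))
                    else:
                        edges.append((labels[i], labels[j], letter))
    return TypedGraph.from_edge_list(config.registry, edges, extra_nodes=labels)


# Outer 5-cycle, spokes, and the inner pentagram of the Petersen graph.
PETERSEN_EDGES: Tuple[Tuple[int, int], ...] = tuple(
    [(i, (i + 1) % 5) for i in range(5)]
    + [(i, i + 5) for i in range(5)]
    + [(5 + i, 5 + (i + 2) % 5) for i in range(5)]
)


def named_fixture(name: str, *, k: int = 3,
                  registry: Optional[Mapping[str, EdgeType]] = None):
    """Canonical fixture graphs and patterns used across the test suite.

    ``petersen`` is a :class:`TypedGraph` (10 nodes, 15 undirected X
    edges, 3-regular); ``clique-k`` and ``cycle-k`` are undirected
    patterns on ``k`` nodes; ``tetrahedron`` (``XxXXXX``) and ``g4``
    (``xXxXxx``) are the directed 4-node patterns.
    """
    if name == "petersen":
        reg = registry or make_registry([("X", False)])
        labels = [f"v{i:02d}" for i in range(10)]
        return TypedGraph.from_edge_list(
            reg, [(labels[a], labels[b], "X") for a, b in PETERSEN_EDGES])
    if name == "clique-k":
        reg = registry or make_registry([("X", False)])
        return parse_pattern("X" * (k * (k - 1) // 2), reg)
    if name == "cycle-k":
        if k < 3:
            raise ValueError("cycle needs k >= 3")
        reg = registry or make_registry([("X", False)])
        edges = [(i, i + 1, "X", None) for i in range(k - 1)] + [(0, k - 1, "X", None)]
        return parse_pattern(tokens_from_edges(k, edges), reg)
    if name == "tetrahedron":
        reg = registry or make_registry([("X", True)])
        return parse_pattern("XxXXXX", reg)
    if name == "g4":
        reg = registry or make_registry([("X", True)])
        return parse_pattern("xXxXxx", reg)
    raise ValueError(f"unknown fixture {name!r}")
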