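"""Shared builders and cross-check helpers for the test suite."""

from __future__ import annotations

import random

import symmatch as sm

REG_X = sm.make_registry([("X", False)])
REG_XD = sm.make_registry([("X", True)])
REG_S = sm.make_registry([("S", True)])
REG_XS = sm.make_registry([("X", False), ("S", True)])


def complete_graph(m: int, registry=None, letter: str = "X") -> sm.TypedGraph:
    """Complete graph on m nodes, labels n00..n{m-1}, one undirected type."""
    registry = registry or REG_X
    return sm.TypedGraph.from_edge_list(
        registry,
        [(f"n{a:02d}", f"n{b:02d}", letter) for a in range(m) for b in range(a + 1, m)])


def petersen_pattern() -> sm.PatternGraph:
    tokens = sm.tokens_from_edges(10, [(a, b, "X", None) for a, b in sm.PETERSEN_EDGES])
    return sm.parse_pattern(tokens, REG_X)


def node_orbits_from_automorphisms(automorphisms, k):
    """Node-orbit partition implied by an explicit automorphism list."""
    parent = list(range(k))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for perm in automorphisms:
        for i in range(k):
            ra, rb = find(i), find(perm[i])
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    cells = {}
    for i in range(k):
        cells.setdefault(find(i), []).append(i)
    return tuple(tuple(sorted(c)) for _, c in sorted(cells.items()))


def oracle_equivalence_check(graph: sm.TypedGraph, pattern: sm.PatternGraph):
    """Assert the matcher returns exactly one member of each Aut-orbit.

    Independently enumerates all matches and all pattern automorphisms by
    brute force, groups the matches into orbits, and checks that the
    matcher output is exactly one representative per orbit and that
    |output| * |Aut| = |matches|.
    """
    matches = sm.brute_force_matches(graph, pattern)
    autos = sm.brute_force_automorphisms(pattern)
    orbits = sm.orbit_partition_of_matches(matches, autos)
    found = [tuple(graph.id_of(label) for label in record)
             for record in sm.find_subgraph_instances(graph, pattern, verify=True)]
    assert len(set(found)) == len(found), "matcher emitted a duplicate instance"
    assert len(found) * len(autos) == len(matches)
    assert len(found) == len(orbits)
    found_set = set(found)
    for orbit in orbits:
        hits = [m for m in orbit if m in found_set]
        assert len(hits) == 1, f"orbit represented {len(hits)} times: {orbit}"
    return len(found), len(matches), len(autos)


def random_trial_graphs(seed: int):
    """One mixed undirected/directed graph and one directed-X graph per seed."""
    rng = random.Random(seed)
    n = rng.randint(10, 25)
    reg1 = sm.make_registry([("X", False), ("S", True)])
    g1 = sm.random_typed_graph(sm.GeneratorConfig(
        n=n,
        densities={"X": rng.uniform(0.10, 0.35), "S": rng.uniform(0.10, 0.35)},
        registry=reg1, seed=seed * 2 + 1))
    reg2 = sm.make_registry([("X", True)])
    g2 = sm.random_typed_graph(sm.GeneratorConfig(
        n=n, densities={"X": rng.uniform(0.10, 0.35)}, registry=reg2, seed=seed * 2 + 2))
    return g1, g2


# Patterns paired with the graph (1 = mixed, 2 = directed-X) they run on.
TRIAL_PATTERNS = [
    ("XXX", 1), ("XX00XX", 1), ("XXXXXX", 1), ("SsS", 1),
    ("XxXXXX", 2), ("xXxXxx", 2),
]


def run_oracle_trial(seed: int):
    g1, g2 = random_trial_graphs(seed)
    for tokens, which in TRIAL_PATTERNS:
        graph = g1 if which == 1 else g2
        pattern = sm.parse_pattern(tokens, graph.registry)
        oracle_equivalence_check(graph, pattern)
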