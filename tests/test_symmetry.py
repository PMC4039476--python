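"""Automorphism detection: partitions, OPP search, constraints, group order."""

import pytest
from hypothesis import given, settings, strategies as st

import symmatch as sm
from helpers import (REG_X, REG_XS, node_orbits_from_automorphisms, petersen_pattern)


def pat(tokens, registry=None):
    return sm.parse_pattern(tokens, registry or REG_X)


MULTI = sm.make_registry([("X", False), ("Z", False), ("Y", False)])
DIRX = sm.make_registry([("X", True)])

# Patterns small enough for exhaustive automorphism enumeration.
SMALL_PATTERNS = [
    pat("XXX"),
    pat("XX0"),
    pat("XX00XX"),
    pat("XXXXXX"),
    pat("XZ00ZY", MULTI),
    pat("SsS", REG_XS),
    pat("xXxXxx", DIRX),
    pat("XxXXXX", DIRX),
    pat("GPs", sm.make_registry([("G", False), ("P", False), ("S", True)])),
    sm.named_fixture("clique-k", k=5),
    sm.named_fixture("cycle-k", k=5),
    sm.named_fixture("cycle-k", k=6),
    pat(sm.tokens_from_edges(5, [(i, i + 1, "X", None) for i in range(4)])),  # 5-chain
    pat(sm.tokens_from_edges(4, [(0, j, "X", None) for j in (1, 2, 3)])),     # star
]


class TestInitialPartition:
    def test_mixed_types_split_into_two_cells(self):
        cells = sm.initial_partition(pat("XZ00ZY", MULTI))
        assert set(map(frozenset, cells)) == {frozenset({0, 1}), frozenset({2, 3})}

    def test_clique_stays_in_one_cell(self):
        assert sm.initial_partition(pat("XXXXXX")) == ((0, 1, 2, 3),)

    def test_path_centre_separated_from_leaves(self):
        cells = sm.initial_partition(pat("XX0"))
        assert set(map(frozenset, cells)) == {frozenset({0}), frozenset({1, 2})}

    def test_partition_is_equitable(self):
        for pattern in SMALL_PATTERNS:
            cells = sm.initial_partition(pattern)
            index = {v: ci for ci, cell in enumerate(cells) for v in cell}
            for cell in cells:
                sigs = set()
                for v in cell:
                    counts = {}
                    for other, letter, role in pattern.incident(v):
                        key = (index[other], letter, role)
                        counts[key] = counts.get(key, 0) + 1
                    sigs.add(tuple(sorted(counts.items())))
                assert len(sigs) == 1


class TestCoupleAndRefine:
    def test_couple_isolates_corresponding_singletons(self):
        p = pat("XX00XX")
        start = sm.initial_partition(p)
        top, bottom = sm.couple((start, start), 0, 2)
        assert top[0] == (0,) and bottom[0] == (2,)
        assert top[1] == (1, 2, 3) and bottom[1] == (0, 1, 3)

    def test_couple_outside_corresponding_cell_rejected(self):
        p = pat("XX0")
        start = sm.initial_partition(p)  # ((0,), (1, 2)) in some order
        with pytest.raises(ValueError):
            sm.couple((start, start), 0, 1)

    def test_coupling_last_pair_of_two_cell(self):
        p = pat("XX0")
        start = sm.initial_partition(p)
        opp = sm.couple((start, start), 1, 2)
        assert any(cell == (1,) for cell in opp[0])
        assert any(cell == (2,) for cell in opp[1])

    def test_ring_refines_to_three_cells_after_identity_coupling(self):
        p = pat("XX00XX")
        start = sm.initial_partition(p)
        refined = sm.refine_opp(sm.couple((start, start), 0, 0), p)
        assert refined is not None
        top, bottom = refined
        assert len(top) == 3 and len(bottom) == 3
        # node 0's two ring neighbours separate from its antipode
        assert set(map(frozenset, top)) == {frozenset({0}), frozenset({1, 2}), frozenset({3})}

    def test_diverging_partitions_pruned(self):
        # top refines to 2 cells, bottom to 3: no bijection can exist
        p = pat("XX0")
        opp = (((0,), (1, 2)), ((1,), (0, 2)))
        assert sm.refine_opp(opp, p) is None


class TestAnalyseSymmetry:
    def test_ring_constraints_and_coset_reps(self):
        res = sm.analyse_symmetry(pat("XX00XX"))
        assert sm.group_order(res.generators, 4) == 8
        assert res.coset_reps[0] == frozenset({0, 1, 2, 3})
        assert res.coset_reps[1] == frozenset({1, 2})
        assert res.constraints == frozenset({(0, 1), (0, 2), (0, 3), (1, 2)})

    def test_asymmetric_pattern_has_identity_group_only(self):
        res = sm.analyse_symmetry(pat("xXxXxx", DIRX))
        assert sm.group_order(res.generators, 4) == 1
        assert res.constraints == frozenset()
        assert res.orbits == ((0,), (1,), (2,), (3,))

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_clique_constraints_form_total_chain(self, k):
        res = sm.analyse_symmetry(sm.named_fixture("clique-k", k=k))
        expected = frozenset((i, j) for i in range(k) for j in range(i + 1, k))
        assert res.constraints == expected

    def test_petersen_group_order_is_120(self):
        res = sm.analyse_symmetry(petersen_pattern())
        assert sm.group_order(res.generators, 10) == 120

    @pytest.mark.parametrize("pattern", SMALL_PATTERNS,
                             ids=[p.tokens for p in SMALL_PATTERNS])
    def test_completeness_against_exhaustive_enumeration(self, pattern):
        """Generated group and orbits equal the brute-force automorphism set."""
        autos = sm.brute_force_automorphisms(pattern)
        res = sm.analyse_symmetry(pattern)
        assert sm.group_order(res.generators, pattern.k) == len(autos)
        assert res.orbits == node_orbits_from_automorphisms(autos, pattern.k)

    @pytest.mark.parametrize("pattern", SMALL_PATTERNS,
                             ids=[p.tokens for p in SMALL_PATTERNS])
    def test_generators_are_sound_automorphisms(self, pattern):
        autos = set(sm.brute_force_automorphisms(pattern))
        res = sm.analyse_symmetry(pattern)
        for g in res.generators:
            assert g in autos

    @pytest.mark.parametrize("pattern", SMALL_PATTERNS,
                             ids=[p.tokens for p in SMALL_PATTERNS])
    def test_orbit_pruning_is_conservative(self, pattern):
        """Disabling orbit pruning changes neither group nor constraints."""
        pruned = sm.analyse_symmetry(pattern, orbit_pruning=True)
        full = sm.analyse_symmetry(pattern, orbit_pruning=False)
        assert pruned.constraints == full.constraints
        assert pruned.orbits == full.orbits
        assert sm.group_order(pruned.generators, pattern.k) == \
               sm.group_order(full.generators, pattern.k)

    def test_constraints_are_acyclic(self):
        from graphlib import TopologicalSorter
        for pattern in SMALL_PATTERNS + [petersen_pattern()]:
            res = sm.analyse_symmetry(pattern)
            graph = {}
            for p, q in res.constraints:
                graph.setdefault(q, []).append(p)
            tuple(TopologicalSorter(graph).static_order())  # raises on a cycle


class TestGenerateConstraints:
    def test_direct_application(self):
        got = sm.generate_constraints({0: frozenset({0, 1, 2, 3})})
        assert got == frozenset({(0, 1), (0, 2), (0, 3)})

    def test_empty_and_singleton_reps(self):
        assert sm.generate_constraints({}) == frozenset()
        assert sm.generate_constraints({2: frozenset({2})}) == frozenset()


class TestGroupOrder:
    def test_trivial_group(self):
        assert sm.group_order([]) == 1

    def test_cyclic_group_from_single_cycle(self):
        assert sm.group_order([(1, 2, 3, 0)]) == 4

    def test_symmetric_group_from_transpositions(self):
        assert sm.group_order([(1, 0, 2, 3), (0, 2, 1, 3), (0, 1, 3, 2)]) == 24


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.data())
def test_orbit_sizes_divide_group_order(data):
    """Lagrange: every match-orbit size divides |Aut| (random small inputs)."""
    seed = data.draw(st.integers(0, 10 ** 6))
    g = sm.random_typed_graph(sm.GeneratorConfig(
        n=10, densities={"X": 0.4}, registry=REG_X, seed=seed))
    pattern = pat(data.draw(st.sampled_from(["XXX", "XX0", "XX00XX"])))
    matches = sm.brute_force_matches(g, pattern)
    autos = sm.brute_force_automorphisms(pattern)
    for orbit in sm.orbit_partition_of_matches(matches, autos):
        assert len(autos) % len(orbit) == 0


def test_symmetry_report_lists_order_orbits_constraints():
    p = pat("XX00XX")
    text = sm.symmetry_report(sm.analyse_symmetry(p), p)
    assert "automorphism group order: 8" in text
    assert "m(1) < m(2)" in text
    assert "orbits" in text
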