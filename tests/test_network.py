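"""Graph data model: DAG validation, blankets, d-separation, moralization,
parameter counting and equivalence classes, cross-checked against
path-enumeration and exhaustive-enumeration oracles."""

import itertools

import numpy as np
import pytest

from bnepi import (
    CycleError,
    NetworkStructure,
    ParameterSet,
    UnknownNodeError,
    count_free_parameters,
    d_separated,
    equivalence_class,
    joint_probability,
    markov_blanket,
    moralize,
    raw_joint_size,
    validate_dag,
)
from bnepi.search import enumerate_dags

from _oracles import dsep_paths_oracle, dsep_signature, random_dag

EX6_EDGES = [("S2", "S1"), ("S3", "E"), ("E", "B"), ("E", "C"), ("S1", "C")]


class TestValidateDag:
    def test_exemplar_order_parents_first(self, exposure6):
        structure, _ = exposure6
        order = validate_dag(structure)
        pos = {v: i for i, v in enumerate(order)}
        for a, b in structure.edges:
            assert pos[a] < pos[b]

    def test_empty_edge_set_keeps_declaration_order(self):
        s = NetworkStructure(["A", "B"])
        assert validate_dag(s) == ["A", "B"]

    def test_two_cycle_rejected_with_explicit_cycle(self):
        with pytest.raises(CycleError) as err:
            NetworkStructure(["A", "B"], None, [("A", "B"), ("B", "A")])
        assert set(err.value.cycle) == {"A", "B"}

    def test_unknown_edge_endpoint_named(self):
        with pytest.raises(UnknownNodeError, match="Z"):
            NetworkStructure(["A", "B"], None, [("A", "Z")])

    def test_self_loop_and_duplicate_edges_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            NetworkStructure(["A"], {"A": ["0", "1"]}, [("A", "A")])


class TestMarkovBlanket:
    @pytest.mark.parametrize(
        "node,expected",
        [
            ("C", {"E", "S1"}),  # parents only, no children
            ("E", {"S3", "B", "C", "S1"}),  # parent + children + spouse
            ("S2", {"S1"}),
        ],
    )
    def test_exemplar_blankets(self, exposure6, node, expected):
        structure, _ = exposure6
        assert markov_blanket(structure, node) == expected

    def test_isolated_node_has_empty_blanket(self):
        s = NetworkStructure(["A", "B", "C"], None, [("A", "B")])
        assert markov_blanket(s, "C") == set()

    def test_noncausal_cancer_blanket(self, bladder11):
        structure, _ = bladder11
        assert markov_blanket(structure, "CANCER") == {
            "GENDER",
            "SMOKER",
            "XRCC3_241",
            "XRCC3_04",
        }

    def test_unknown_node(self, bladder11):
        with pytest.raises(UnknownNodeError):
            markov_blanket(bladder11[0], "NOPE")


class TestDSeparation:
    @pytest.mark.parametrize(
        "X,Z,Y,expected",
        [
            ({"B", "C"}, {"S3"}, {"E"}, True),  # serial paths through E
            ({"C"}, {"S2"}, {"S1"}, True),  # serial path through S1
            ({"E"}, {"S1"}, {"C"}, False),  # conditioning on collider opens
            ({"E"}, {"S1"}, set(), True),  # unconditioned collider blocks
        ],
    )
    def test_exemplar_relations(self, exposure6, X, Z, Y, expected):
        structure, _ = exposure6
        assert d_separated(structure, X, Z, Y) is expected

    def test_rejects_overlapping_or_empty_sets(self, exposure6):
        s, _ = exposure6
        with pytest.raises(ValueError):
            d_separated(s, {"E"}, {"E"}, set())
        with pytest.raises(ValueError):
            d_separated(s, set(), {"E"}, set())

    def test_agrees_with_path_enumeration_oracle_on_random_dags(self):
        """Singleton and set-valued triples on random DAGs up to 6 nodes."""
        rng = np.random.default_rng(20260918)
        for n in (3, 4, 5, 6):
            for _ in range(4):
                s = random_dag(rng, n)
                nodes = list(s.nodes)
                for x, z in itertools.combinations(nodes, 2):
                    rest = [v for v in nodes if v not in (x, z)]
                    for r in range(len(rest) + 1):
                        for cond in itertools.combinations(rest, r):
                            got = d_separated(s, {x}, {z}, set(cond))
                            want = dsep_paths_oracle(s, {x}, {z}, set(cond))
                            assert got == want, (s.edges, x, z, cond)
                # a few random set-valued triples per graph
                for _ in range(10):
                    labels = rng.integers(0, 4, size=n)
                    X = {v for v, l in zip(nodes, labels) if l == 0}
                    Z = {v for v, l in zip(nodes, labels) if l == 1}
                    Y = {v for v, l in zip(nodes, labels) if l == 2}
                    if not X or not Z:
                        continue
                    assert d_separated(s, X, Z, Y) == dsep_paths_oracle(s, X, Z, Y)

    def test_symmetry_in_x_and_z(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            s = random_dag(rng, 5)
            nodes = list(s.nodes)
            X, Z, Y = {nodes[0]}, {nodes[1], nodes[2]}, {nodes[3]}
            assert d_separated(s, X, Z, Y) == d_separated(s, Z, X, Y)

    def test_markov_blanket_shields(self):
        """v is d-separated from every non-blanket node by its blanket."""
        rng = np.random.default_rng(11)
        for _ in range(15):
            s = random_dag(rng, 6)
            for v in s.nodes:
                mb = markov_blanket(s, v)
                for w in s.nodes:
                    if w == v or w in mb:
                        continue
                    assert d_separated(s, {v}, {w}, mb)


class TestJointProbability:
    def test_normalization_over_all_assignments(self, exposure6):
        structure, params = exposure6
        total = sum(
            joint_probability(structure, params, dict(zip(structure.nodes, combo)))
            for combo in itertools.product("01", repeat=6)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_uniform_cpts_give_uniform_joint(self):
        s = NetworkStructure(list("ABCDEF"), None, EX6_EDGES_RENAMED)
        p = ParameterSet.uniform(s)
        a = dict(zip(s.nodes, "010101"))
        assert joint_probability(s, p, a) == pytest.approx(1 / 64)

    def test_equals_explicit_factorized_product(self, exposure6):
        structure, params = exposure6
        a = {"S1": "1", "S2": "0", "S3": "1", "E": "1", "B": "0", "C": "1"}
        expected = (
            params.prob("B", "0", a)
            * params.prob("C", "1", a)
            * params.prob("E", "1", a)
            * params.prob("S1", "1", a)
            * params.prob("S3", "1", a)
            * params.prob("S2", "0", a)
        )
        assert joint_probability(structure, params, a) == pytest.approx(expected)

    def test_incomplete_assignment_rejected(self, exposure6):
        structure, params = exposure6
        with pytest.raises(ValueError, match="incomplete"):
            joint_probability(structure, params, {"S1": "0"})


# six-node exemplar re-labelled for the uniform-CPT check
EX6_EDGES_RENAMED = [("B", "A"), ("C", "D"), ("D", "E"), ("D", "F"), ("A", "F")]


class TestParameterCounting:
    def test_factored_count_is_12_against_64_raw(self, exposure6):
        structure, _ = exposure6
        assert count_free_parameters(structure) == 12
        assert raw_joint_size(structure) == 64

    def test_empty_graph_counts_one_per_binary_node(self):
        s = NetworkStructure(list("ABCDE"))
        assert count_free_parameters(s) == 5

    def test_fully_connected_six_binary_nodes(self):
        nodes = list("ABCDEF")
        edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        s = NetworkStructure(nodes, None, edges)
        assert count_free_parameters(s) == 63  # 2^6 - 1

    def test_monotone_under_edge_addition(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            s = random_dag(rng, 5, p_edge=0.3)
            before = count_free_parameters(s)
            # add any admissible edge
            for a, b in itertools.permutations(s.nodes, 2):
                if (a, b) in s.edges or (b, a) in s.edges:
                    continue
                try:
                    bigger = s.with_edges(add=[(a, b)])
                except ValueError:
                    continue
                assert count_free_parameters(bigger) >= before


class TestMoralize:
    def test_exemplar_marries_coparents(self, exposure6):
        structure, _ = exposure6
        expected = {
            frozenset(e)
            for e in EX6_EDGES + [("E", "S1")]  # E and S1 share child C
        }
        assert moralize(structure) == expected

    def test_no_common_children_keeps_edge_count(self):
        s = NetworkStructure(list("ABC"), None, [("A", "B"), ("B", "C")])
        assert len(moralize(s)) == 2

    def test_equals_union_of_markov_blanket_links(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            s = random_dag(rng, 6)
            via_blankets = {
                frozenset((v, w))
                for v in s.nodes
                for w in markov_blanket(s, v)
            }
            assert moralize(s) == via_blankets


class TestEquivalenceClass:
    def test_chain_is_fully_reversible(self):
        s = NetworkStructure(list("ABC"), None, [("A", "B"), ("B", "C")])
        pg = equivalence_class(s)
        assert pg.directed == set()
        assert pg.undirected == {frozenset("AB"), frozenset("BC")}

    def test_collider_is_fully_compelled(self):
        s = NetworkStructure(list("ABC"), None, [("A", "C"), ("B", "C")])
        pg = equivalence_class(s)
        assert pg.directed == {("A", "C"), ("B", "C")}
        assert pg.undirected == set()

    def test_exemplar_collider_edges_compelled(self, exposure6):
        structure, _ = exposure6
        pg = equivalence_class(structure)
        assert ("E", "C") in pg.directed
        assert ("S1", "C") in pg.directed

    def test_classes_match_dsep_relations_exhaustively(self):
        """On all 3- and 4-node DAGs: same CPDAG iff same d-separations."""
        for nodes in (list("ABC"), list("ABCD")):
            groups = {}
            for edges in enumerate_dags(nodes):
                s = NetworkStructure(nodes, None, edges)
                pg = equivalence_class(s)
                key = (frozenset(pg.directed), frozenset(pg.undirected))
                groups.setdefault(key, []).append(dsep_signature(s))
            seen_signatures = {}
            for key, sigs in groups.items():
                # same CPDAG -> identical d-separations
                assert all(sig == sigs[0] for sig in sigs)
                # different CPDAG -> different d-separations
                assert sigs[0] not in seen_signatures.values()
                seen_signatures[key] = sigs[0]
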