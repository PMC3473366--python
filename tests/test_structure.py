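"""Dependency matrix, motif enumeration, and feedback functionality."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_model, random_small_model
from lddr.model import interaction_graph
from lddr.structure import (Coherence, DependencyClass, FeedbackLoop, Gate,
                            dependency_matrix, enumerate_feedback_loops,
                            enumerate_ffls, functional_feedback_loops,
                            functionality_context, nodes_on_negative_cycles,
                            signed_reachability)
from lddr.synth import GeneratorConfig, PlantedFFL, random_model
from oracles import (brute_ffl_triples, brute_loop_functional,
                     brute_simple_cycles, brute_simple_paths,
                     brute_walk_reachability,
                     expected_dependency_class as _expected_class)


class TestSignedReachability:
    def test_chain_with_inhibition(self):
        model = build_model(3, [("B", [("A", False, 1)], 1, 1),
                                ("C", [("B", True, 1)], 1, 1)])
        table = signed_reachability(interaction_graph(model))
        assert table[("A", "C")] == (False, True)

    def test_parallel_paths_of_both_signs(self):
        model = build_model(3, [("B", [("A", False, 1)], 1, 1),
                                ("C", [("A", True, 1)], 1, 1),
                                ("B", [("C", False, 1)], 1, 1)])
        table = signed_reachability(interaction_graph(model))
        assert table[("A", "B")] == (True, True)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6))
    def test_matches_walk_enumeration_oracle(self, seed):
        model = random_small_model(seed, n=8, terms=12)
        table = signed_reachability(interaction_graph(model))
        oracle = brute_walk_reachability(model)
        for pair, flags in table.items():
            assert flags == oracle.get(pair, (False, False))


class TestDependencyMatrix:
    def test_acyclic_inhibition_chain_is_strong(self):
        model = build_model(3, [("B", [("A", False, 1)], 1, 1),
                                ("C", [("B", True, 1)], 1, 1)])
        matrix = dependency_matrix(interaction_graph(model))
        assert matrix[("A", "C")] == DependencyClass.STRONG_INHIBITOR
        assert matrix[("C", "A")] == DependencyClass.NO_EFFECT

    def test_negative_selfloop_on_intermediate_makes_downstream_weak(self):
        """A -> B -> C with B -| B: the only simple A->C path is positive,
        but B sits on a negative loop, so A is a weak activator of C."""
        model = build_model(3, [("B", [("A", False, 1)], 1, 1),
                                ("B", [("B", True, 1)], 1, 1),
                                ("C", [("B", False, 1)], 1, 1)])
        matrix = dependency_matrix(interaction_graph(model))
        assert matrix[("A", "C")] == DependencyClass.WEAK_ACTIVATOR
        assert matrix[("B", "B")] == DependencyClass.WEAK_INHIBITOR

    def test_acyclic_graphs_have_no_weak_classes(self):
        model = random_model(GeneratorConfig(
            n_components=8, n_terms=12, forbid_negative_cycles=True,
            forbid_positive_cycles=True, negation_probability=0.4, seed=5))
        matrix = dependency_matrix(interaction_graph(model))
        assert not any(cls in (DependencyClass.WEAK_ACTIVATOR,
                               DependencyClass.WEAK_INHIBITOR)
                       for cls in matrix.values())

    def test_every_ordered_pair_is_classified(self):
        model = random_small_model(11, n=7, terms=10)
        graph = interaction_graph(model)
        matrix = dependency_matrix(graph)
        assert set(matrix) == {(i, j) for i in graph.nodes for j in graph.nodes}

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6))
    def test_matches_simple_path_and_cycle_oracle(self, seed):
        model = random_small_model(seed, n=8, terms=12)
        matrix = dependency_matrix(interaction_graph(model))
        paths = brute_simple_paths(model)
        neg_nodes = {n for cyc, s in brute_simple_cycles(model) if s < 0
                     for n in cyc}
        for pair, cls in matrix.items():
            signs, members = paths.get(pair, (set(), set()))
            assert cls == _expected_class(signs, members, neg_nodes), pair


class TestFeedForwardLoops:
    def test_or_gated_coherent_type1(self):
        """Activation of a target by either the direct or the indirect
        regulator (distinct terms) is a coherent type-1 FFL with OR gate."""
        model = build_model(3, [("B", [("A", False, 1)], 1, 1),
                                ("C", [("B", False, 1)], 1, 1),
                                ("C", [("A", False, 1)], 1, 1)])
        (rec,) = enumerate_ffls(model)
        assert (rec.x, rec.y, rec.z) == ("A", "B", "C")
        assert rec.coherence is Coherence.COHERENT
        assert rec.type_index == 1
        assert rec.gate is Gate.OR

    def test_incoherent_classification(self):
        model = build_model(3, [("B", [("A", False, 1)], 1, 1),
                                ("C", [("B", True, 1)], 1, 1),
                                ("C", [("A", False, 1)], 1, 1)])
        (rec,) = enumerate_ffls(model)
        assert rec.coherence is Coherence.INCOHERENT
        assert rec.signs == (1, -1, 1)
        assert rec.type_index == 3

    def test_and_gate_when_literals_cooccur(self):
        model = build_model(3, [("B", [("A", False, 1)], 1, 1),
                                ("C", [("A", False, 1), ("B", False, 1)], 1, 1)])
        (rec,) = enumerate_ffls(model)
        assert rec.gate is Gate.AND

    @pytest.mark.parametrize("signs, gate, type_index, coherent", [
        ((1, 1, 1), "AND", 1, True),
        ((1, 1, 1), "OR", 1, True),
        ((-1, -1, 1), "AND", 2, True),
        ((1, -1, 1), "OR", 3, False),
        ((-1, 1, -1), "AND", 4, True),
    ])
    def test_planted_ffl_recovered_exactly_once(self, signs, gate, type_index,
                                                coherent):
        model = random_model(GeneratorConfig(
            n_components=5, n_terms=6, seed=9,
            planted_motifs=(PlantedFFL(signs=signs, gate=gate),)))
        hits = [r for r in enumerate_ffls(model)
                if r.x.startswith("m") and r.x[1:].isdigit()]
        assert len(hits) == 1
        rec = hits[0]
        assert rec.signs == signs
        assert rec.gate.value == gate
        assert rec.type_index == type_index
        assert (rec.coherence is Coherence.COHERENT) == coherent

    def test_coherence_consistent_with_sign_product(self):
        for seed in range(15):
            model = random_small_model(seed, n=7, terms=12)
            for rec in enumerate_ffls(model):
                s_xy, s_yz, s_xz = rec.signs
                assert (rec.coherence is Coherence.COHERENT) == \
                    (s_xz == s_xy * s_yz)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6))
    def test_triples_match_brute_force(self, seed):
        model = random_small_model(seed, n=7, terms=12)
        mine = {(r.x, r.y, r.z, *r.signs) for r in enumerate_ffls(model)}
        assert mine == {t for t in brute_ffl_triples(model)
                        if t[0] != t[1] and t[1] != t[2] and t[0] != t[2]}


class TestFeedbackLoops:
    def test_inhibitor_expression_motif_is_one_negative_two_cycle(self):
        """A transcription factor driving its own inhibitor: one negative
        feedback loop of length 2 (the NF-κB/IκBα motif shape)."""
        model = build_model(2, [("B", [("A", False, 1)], 1, 1),
                                ("A", [("B", True, 1)], 1, 1)])
        loops = enumerate_feedback_loops(interaction_graph(model))
        assert len(loops) == 1
        assert loops[0].nodes == ("A", "B")
        assert loops[0].sign == -1

    def test_double_activation_is_a_positive_cycle(self):
        model = build_model(2, [("B", [("A", False, 1)], 1, 1),
                                ("A", [("B", False, 1)], 1, 1)])
        (loop,) = enumerate_feedback_loops(interaction_graph(model))
        assert loop.sign == 1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6))
    def test_cycle_sets_match_brute_force(self, seed):
        model = random_small_model(seed, n=7, terms=12)
        graph = interaction_graph(model)
        mine = {(l.nodes, l.sign) for l in enumerate_feedback_loops(graph, 7)}
        assert mine == brute_simple_cycles(model)

    def test_negative_cycle_membership(self):
        model = build_model(3, [("B", [("A", False, 1)], 1, 1),
                                ("A", [("B", True, 1)], 1, 1),
                                ("C", [("C", False, 1)], 1, 1)])
        assert nodes_on_negative_cycles(interaction_graph(model)) == {"A", "B"}


class TestFunctionality:
    def test_and_cofactor_gates_the_context(self):
        """A two-cycle whose forward arc needs an AND co-factor is
        functional exactly when the co-factor is present."""
        model = build_model(3, [("B", [("A", False, 1), ("C", False, 1)], 1, 1),
                                ("A", [("B", True, 1)], 1, 1)])
        loop = FeedbackLoop(("A", "B"), -1)
        assert functionality_context(model, loop) == [{"C": 1}]

    def test_shadowing_or_term_kills_functionality(self):
        """If an always-on OR alternative drives the target regardless of
        the loop arc's source, the loop is non-functional in that context."""
        model = build_model(3, [("B", [("A", False, 1)], 1, 1),
                                ("B", [("C", False, 1)], 1, 1),
                                ("A", [("B", True, 1)], 1, 1)])
        loop = FeedbackLoop(("A", "B"), -1)
        assert functionality_context(model, loop) == [{"C": 0}]

    def test_self_loop_context(self):
        model = build_model(2, [("B", [("A", False, 1), ("B", True, 1)], 1, 1)])
        loop = FeedbackLoop(("B",), -1)
        assert functionality_context(model, loop) == [{"A": 1}]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6))
    def test_functionality_matches_state_space_derivative_oracle(self, seed):
        model = random_small_model(seed, n=5, terms=8)
        graph = interaction_graph(model)
        for loop in enumerate_feedback_loops(graph, 5):
            contexts = functionality_context(model, loop)
            from lddr.structure import external_regulators
            externals = external_regulators(model, loop)
            import itertools as it
            for combo in it.product(*(model.levels(r) for r in externals)):
                context = dict(zip(externals, combo))
                assert (context in contexts) == brute_loop_functional(
                    model, list(loop.nodes), context)
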