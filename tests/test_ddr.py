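"""The damage-response models: core attractors, scenario reports, searches."""

import pytest

from lddr.ddr import (APOPTOSIS, ARREST, CORE_VARIANTS, NFKB,
                      carcinogenic_defect_search, compare, core_attractors,
                      core_model, damage_initial_state, ddr_priority_scheme,
                      load_full_model, scenario_registry,
                      sensitization_target_search, synthetic_ddr_network)
from lddr.dynamics import AttractorKind, steady_states_symbolic
from lddr.errors import ModelValidationError, TranscriptionMissingError
from lddr.model import interaction_graph, serialize_model
from lddr.steady import UNDETERMINED, active_terms, logical_steady_state
from lddr.structure import functional_feedback_loops


class TestCoreModel:
    def test_six_components_in_figure_order(self):
        model = core_model()
        assert list(model.components) == [
            "DSBs_early", "DSBs_late", "RPA-ATR-ATRIP-P", "ATM-P", "p53-P",
            NFKB]

    def test_wildtype_enters_a_complex_cyclic_attractor(self):
        (attractor,) = core_attractors("wildtype")
        assert attractor.kind is AttractorKind.COMPLEX_LOOP

    @pytest.mark.parametrize("variant", ["nfkb_constitutive", "p53_deficient"])
    def test_single_feedback_interruptions_keep_cycling(self, variant):
        (attractor,) = core_attractors(variant)
        assert attractor.kind in (AttractorKind.SIMPLE_LOOP,
                                  AttractorKind.COMPLEX_LOOP)

    @pytest.mark.parametrize("variant", ["p53_deficient_nfkb_constitutive",
                                         "p53_constitutive"])
    def test_double_interruption_or_constitutive_p53_freezes(self, variant):
        (attractor,) = core_attractors(variant)
        assert attractor.kind is AttractorKind.STEADY_STATE

    def test_each_variant_has_exactly_one_attractor(self):
        for variant in CORE_VARIANTS:
            assert len(core_attractors(variant)) == 1

    def test_fixed_point_presence_matches_attractor_kind(self):
        """Scheme-independent fixed-point search agrees with the STG view:
        cyclic variants have no fixed point under damage, frozen variants
        have exactly one."""
        for variant, clamps in CORE_VARIANTS.items():
            model = core_model().with_clamps(clamps)
            points = steady_states_symbolic(model, {"DSBs_early": 1})
            (attractor,) = core_attractors(variant)
            if attractor.kind is AttractorKind.STEADY_STATE:
                assert len(points) == 1
            else:
                assert points == []

    def test_core_feedback_loops_are_all_negative_and_functional(self):
        loops = functional_feedback_loops(core_model(), 6)
        assert loops
        assert all(l.sign == -1 for l in loops)


@pytest.fixture(scope="module")
def model():
    return synthetic_ddr_network()


class TestSyntheticNetwork:
    def test_validates_and_has_ternary_trio(self, model):
        ternary = {n for n, c in model.components.items() if c.max_level == 2}
        assert ternary == {"ATM-P", "IKK_complex-P", "IκBα"}

    def test_basal_state_without_damage(self, model):
        """No stimulus: basal IKK partially degrades IκBα, c-Rel is active,
        the damage-inducible arms and both outputs stay off."""
        state = logical_steady_state(model, {}, 2)
        assert state["IκBα"] == 1
        assert state["c-Rel"] == 1
        assert state[NFKB] == 0
        assert state[ARREST] == 0
        assert state[APOPTOSIS] == 0

    def test_dsb_response_activates_all_survival_arms(self, model):
        state = logical_steady_state(model, {"DSBs_early": 1}, 2)
        assert state["ATM-P"] == 2
        assert state["IκBα"] == 0
        assert state[NFKB] == 1
        assert state[ARREST] == 1
        assert state[APOPTOSIS] == 1

    def test_atm_loss_under_dsbs_blocks_survival_signalling(self, model):
        """The published loss-of-ATM phenotype: arrest, NF-κB and p53
        activation all blocked while one apoptosis route survives."""
        report = compare(model, scenario_registry()["ATM_loss_dsb"])
        assert f"{ARREST} blocked" in report.verdicts
        assert f"{NFKB} blocked" in report.verdicts
        assert "p53-P blocked" in report.verdicts
        assert report.pathway_counts[APOPTOSIS] == (3, 1)

    def test_chk1_loss_under_ssbs_halves_cdc25a_degradation(self, model):
        report = compare(model, scenario_registry()["Chk1_loss_ssb"])
        assert report.pathway_counts["Cdc25A_degradation"] == (2, 1)
        assert any(v.startswith("Cdc25A_degradation diminished")
                   for v in report.verdicts)

    def test_mrn_subunit_disorders_are_indistinguishable(self, model):
        registry = scenario_registry()
        reports = [compare(model, registry[name]) for name in
                   ("atm_like_disorder", "nijmegen_breakage_syndrome",
                    "nbs_like_disorder")]
        assert reports[0].level_changes == reports[1].level_changes \
            == reports[2].level_changes

    def test_late_feedback_layer_shuts_p53_axis_down(self, model):
        """At the full cutoff the Wip1/MDM2 feedback entangles the p53 axis
        in unresolved negative loops (no steady p53 level), while the
        cutoff-2 view keeps it determined and active."""
        mid = logical_steady_state(model, {"DSBs_early": 1}, 2)
        late = logical_steady_state(model, {"DSBs_early": 1}, 3)
        assert mid["p53-P"] == 1
        assert late["p53-P"] is UNDETERMINED
        assert late["Wip1"] is UNDETERMINED


class TestCoreConsistency:
    def test_subnetwork_reduction_agrees_with_the_hand_built_core(self, model):
        """Reducing the synthetic subnetwork onto the six core components
        (housekeeping inputs pinned, outputs pruned) yields the same
        qualitative picture as the hand-built core: the key negative
        feedback arcs survive, and there is no fixed point under damage —
        the structural signature of the core's cyclic attractor."""
        from lddr.reduction import reduce_to

        keep = ["DSBs_early", "DSBs_late", "RPA-ATR-ATRIP-P", "ATM-P",
                "p53-P", NFKB]
        reduced = reduce_to(model, keep,
                            clamps={"SSBs": 0, "Hsp90": 1, "HIPK2": 1})
        assert set(reduced.components) == set(keep)
        arcs = {(a.source, a.target, a.sign)
                for a in interaction_graph(reduced).arcs}
        assert ("p53-P", "ATM-P", -1) in arcs        # Wip1 layer, folded
        assert ("p53-P", "p53-P", -1) in arcs        # Wip1/MDM2 self-loop
        assert (NFKB, NFKB, -1) in arcs              # IκBα layer, folded
        assert ("ATM-P", NFKB, 1) in arcs
        assert steady_states_symbolic(reduced, {"DSBs_early": 1}) == []
        # and with damage off, the basal state is the unique fixed point
        basal = steady_states_symbolic(reduced, {"DSBs_early": 0})
        assert len(basal) == 1


class TestSearches:
    def test_atm_deficient_dsb_scenario_needs_no_targets(self, model):
        """ATM loss alone already blocks both survival arms while leaving
        an apoptosis route intact, so the search reports no targets."""
        sets = sensitization_target_search(
            model, scenario_registry()["ATM_loss_dsb"])
        assert sets == []

    def test_p53_mutant_dsb_targets_include_atm_singleton(self, model):
        sets = sensitization_target_search(
            model, scenario_registry()["p53_loss_dsb"])
        notations = [s.notation() for s in sets]
        assert "ATM-P" in notations
        assert "PP5" in notations

    def test_hipk2_mutant_dsb_targets(self, model):
        sets = sensitization_target_search(
            model, scenario_registry()["HIPK2_loss_dsb"])
        assert [s.notation() for s in sets] == ["ATM-P", "MRN", "PP5"]

    def test_reported_sets_block_survival_but_not_apoptosis(self, model):
        registry = scenario_registry()
        for s in sensitization_target_search(model, registry["p53_loss_ssb"]):
            clamps = {**registry["p53_loss_ssb"].clamps, **s.as_dict()}
            state = logical_steady_state(model, clamps, 2)
            assert state[ARREST] == 0
            assert state[NFKB] == 0
            assert state[APOPTOSIS] == 1

    def test_defect_search_reports_nonempty_combinations(self, model):
        sets = carcinogenic_defect_search(model, max_cardinality=2)
        assert sets
        assert all(len(s.clamps) >= 1 for s in sets)
        assert any(level > 0 for s in sets for _, level in s.clamps)


class TestFullModelLoader:
    def test_missing_transcription_raises_with_instructions(self, tmp_path):
        with pytest.raises(TranscriptionMissingError, match="transcribe"):
            load_full_model(tmp_path / "full_model.json")

    def test_wrong_census_is_rejected(self, tmp_path):
        path = tmp_path / "full_model.json"
        path.write_text(serialize_model(synthetic_ddr_network()),
                        encoding="utf-8")
        with pytest.raises(ModelValidationError, match="96 components"):
            load_full_model(path)

    def test_bundled_subnetwork_fixture_matches_the_builder(self):
        from importlib import resources

        text = (resources.files("lddr") / "data" /
                "ddr_synthetic_subnetwork.json").read_text(encoding="utf-8")
        assert text == serialize_model(synthetic_ddr_network())

    def test_bundled_core_fixture_matches_the_builder(self):
        from importlib import resources

        text = (resources.files("lddr") / "data" /
                "core_model.json").read_text(encoding="utf-8")
        assert text == serialize_model(core_model())
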