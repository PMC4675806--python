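"""Component patterns, composition operators and model invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import petrilearn as pl
from petrilearn.petri import (InvalidParameterError, ModelInvariantError,
                              PatternError, Species, species_key)


class TestPatterns:
    def test_binding_creates_complex_from_the_two_reactants(self):
        comp = pl.make_binding_component("A", "E", 0.53)
        assert comp.pattern == "binding"
        assert comp.reaction_string() == "A + E -> A|E"
        assert comp.transition.rate_constant == 0.53
        cplx = [s for s in comp.species if s.kind == "complex"][0]
        assert set(cplx.constituents) == {"A", "E"}

    def test_binding_canonicalises_constituent_order(self):
        a = pl.make_binding_component("RKIP", "Raf1", 1.0)
        b = pl.make_binding_component("Raf1", "RKIP", 1.0)
        ca = [s for s in a.species if s.kind == "complex"][0]
        cb = [s for s in b.species if s.kind == "complex"][0]
        assert ca.label == cb.label == "RKIP|Raf1"
        assert ca.key == cb.key

    def test_homodimer_binding_uses_stoichiometry_two(self):
        comp = pl.make_binding_component("A", "A", 0.1)
        assert dict(comp.transition.inputs) == {"A": 2}
        assert comp.reaction_string() == "2 A -> A|A"

    @pytest.mark.parametrize("k", [0.0, -1.0])
    def test_non_positive_rate_rejected(self, k):
        with pytest.raises(InvalidParameterError):
            pl.make_binding_component("A", "E", k)
        with pytest.raises(InvalidParameterError):
            pl.make_unbinding_component("A|E", "reverse", k)

    def test_unbinding_reverse_releases_the_constituents(self):
        comp = pl.make_unbinding_component("A|E", "reverse", 2.0)
        assert comp.reaction_string() == "A|E -> A + E"

    def test_unbinding_convert_phosphorylates_first_constituent(self):
        comp = pl.make_unbinding_component("A|E", "convert", 3.0)
        assert comp.reaction_string() == "A|E -> AP + E"
        rkip = pl.make_unbinding_component(
            "RKIPP|Raf1", "convert", 1.0, constituents=("RKIPP", "Raf1"))
        assert rkip.reaction_string() == "RKIPP|Raf1 -> RKIPPP + Raf1"

    def test_unbinding_rejects_non_binary_complexes(self):
        with pytest.raises(PatternError):
            pl.make_unbinding_component("A", "reverse", 1.0)
        with pytest.raises(PatternError):
            pl.make_unbinding_component("A|B|C", "convert", 1.0)


class TestDecomposition:
    def test_enzymatic_decomposition_yields_the_three_components(self):
        comps = pl.decompose_enzymatic("A", "E")
        assert [c.reaction_string() for c in comps] == [
            "A + E -> A|E", "A|E -> A + E", "A|E -> AP + E"]
        assert [c.pattern for c in comps] == [
            "binding", "unbinding_reverse", "unbinding_convert"]

    def test_erk_mekpp_decomposition(self):
        strings = [c.reaction_string()
                   for c in pl.decompose_enzymatic("ERK", "MEKPP")]
        assert "ERK + MEKPP -> ERK|MEKPP" in strings
        assert "ERK|MEKPP -> ERKP + MEKPP" in strings

    @pytest.mark.parametrize("species,enzymes,expected", [
        (["A"], ["E"], 3),
        (["A", "B"], ["E", "F"], 12),
        ([], ["E"], 0),
    ])
    def test_library_size(self, species, enzymes, expected):
        assert len(pl.build_component_library(species, enzymes, 1.0)) == expected

    def test_library_ordering_is_deterministic(self):
        a = pl.build_component_library(["B", "A"], ["F", "E"], 1.0)
        b = pl.build_component_library(["A", "B"], ["E", "F"], 1.0)
        assert [c.reaction_string() for c in a] == [c.reaction_string() for c in b]


class TestComposition:
    def test_add_single_component(self):
        m = pl.add_component(pl.PetriNetModel(), pl.make_binding_component("A", "E", 1.0))
        assert len(m.places) == 3 and len(m.transitions) == 1

    def test_three_components_compose_to_the_enzymatic_model(self):
        m = pl.model_from_components(pl.decompose_enzymatic("A", "E"))
        assert sorted(m.place_labels()) == ["A", "AP", "A|E", "E"]
        assert len(m.transitions) == 3

    def test_duplicate_addition_is_skipped(self):
        comp = pl.make_binding_component("A", "E", 1.0)
        m1 = pl.add_component(pl.PetriNetModel(), comp)
        m2 = pl.add_component(m1, comp)
        assert m1 == m2

    def test_merging_is_order_insensitive_for_complexes(self):
        m = pl.add_component(pl.PetriNetModel(),
                             pl.make_binding_component("RKIP", "Raf1", 1.0))
        rev = pl.make_unbinding_component("Raf1|RKIP", "reverse", 1.0)
        m2 = pl.add_component(m, rev)
        # the complex place merged, no new complex place was created
        assert len(m2.places) == 3 and len(m2.transitions) == 2

    def test_subtraction_prunes_orphan_places(self, toy_bundle):
        model = toy_bundle.model
        idx = next(i for i, t in enumerate(model.transitions)
                   if "AP" in t.output_multiset)
        sub = pl.subtract_component(model, idx)
        assert sorted(sub.place_labels()) == ["A", "A|E", "E"]
        assert len(sub.transitions) == 2

    def test_subtracting_last_transition_empties_the_model(self):
        m = pl.add_component(pl.PetriNetModel(), pl.make_binding_component("A", "E", 1.0))
        empty = pl.subtract_component(m, 0)
        assert not empty.transitions and not empty.places

    def test_subtract_on_empty_model_is_noop(self):
        empty = pl.PetriNetModel()
        out = pl.subtract_component(empty, 0)
        assert not out.transitions and not out.places
        assert "no-op" in out.history[-1]

    def test_merged_places_keep_existing_initial_concentration(self):
        m = pl.add_component(pl.PetriNetModel(), pl.make_binding_component("A", "E", 1.0))
        m.set_initial("A", 2.5)
        m2 = pl.add_component(m, pl.make_unbinding_component("A|E", "convert", 1.0))
        assert m2.initial_concentrations()["A"] == 2.5

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 11), min_size=1, max_size=8),
           st.integers(0, 11))
    def test_add_then_subtract_restores_transition_multiset(self, picks, extra):
        lib = pl.build_component_library(["A", "B"], ["E", "F"], 1.0)
        model = pl.PetriNetModel()
        for i in picks:
            model = pl.add_component(model, lib[i])
        comp = lib[extra]
        before = sorted(t.signature for t in model.transitions)
        grown = pl.add_component(model, comp)
        if len(grown.transitions) == len(model.transitions):
            return  # duplicate add: nothing to undo
        idx = next(i for i, t in enumerate(grown.transitions)
                   if t.signature == comp.transition.signature)
        back = pl.subtract_component(grown, idx)
        assert sorted(t.signature for t in back.transitions) == before
        pl.validate_model(back)

    def test_validator_rejects_orphans_and_duplicates(self):
        m = pl.model_from_components(pl.decompose_enzymatic("A", "E"))
        m.places[species_key("Z")] = Species.make("Z")
        with pytest.raises(ModelInvariantError):
            pl.validate_model(m)

    def test_transition_rejects_species_on_both_sides(self):
        with pytest.raises(ModelInvariantError):
            pl.Transition(id="bad", inputs=(("A", 1),), outputs=(("A", 1),),
                          rate_constant=1.0)
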