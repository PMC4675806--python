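"""Fitness calculus: coverage f1, spuriousness f2, combined F, behaviour
distance, and interaction coverage."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import petrilearn as pl
from petrilearn.qualitative import (QualitativeState, QualitativeValue,
                                    StateSet, enumerate_universe)


def _subset(universe, n, skip=0):
    states = sorted(universe, key=lambda s: tuple(str(v) for v in s))
    return StateSet(variables=universe.variables,
                    states=frozenset(states[skip:skip + n]))


class TestQualitativeFitness:
    def test_full_coverage_of_reference_states_gives_f1_one(self):
        qs_t = pl.table1_states()
        universe = enumerate_universe(qs_t.variables)
        res = pl.qualitative_fitness(qs_t, qs_t, universe)
        assert res.f1 == 1.0
        assert res.f2 == pytest.approx(14 / 6**4)

    def test_half_coverage(self):
        qs_t = pl.table1_states()
        half = _subset(qs_t, 7)
        res = pl.qualitative_fitness(half, qs_t)
        assert res.f1 == 0.5

    @pytest.mark.parametrize("f1,f2,expected", [
        (1.0, 0.0, 2 / 3),
        (0.0, 0.0, 0.5),
        (0.0, 1.0, 1 / 3),
    ])
    def test_combined_fitness_reference_points(self, f1, f2, expected):
        assert pl.fitness_F(f1, f2) == pytest.approx(expected)

    def test_F_monotone_on_grid(self):
        grid = np.linspace(0, 1, 101)
        for f2 in (0.0, 0.37, 1.0):
            values = [pl.fitness_F(f1, f2) for f1 in grid]
            assert all(b > a for a, b in zip(values, values[1:]))
        for f1 in (0.0, 0.37, 1.0):
            values = [pl.fitness_F(f1, f2) for f2 in grid]
            assert all(b < a for a, b in zip(values, values[1:]))

    def test_attainable_range_is_third_to_two_thirds(self):
        grid = np.linspace(0, 1, 101)
        values = [pl.fitness_F(a, b) for a, b in itertools.product(grid, grid)]
        assert min(values) >= 1 / 3 - 1e-12
        assert max(values) <= 2 / 3 + 1e-12

    def test_mismatched_variable_vectors_error(self):
        a = enumerate_universe(("A",))
        b = enumerate_universe(("B",))
        with pytest.raises(ValueError):
            pl.qualitative_fitness(a, b)

    def test_empty_target_errors(self):
        u = enumerate_universe(("A",))
        empty = StateSet(variables=("A",), states=frozenset())
        with pytest.raises(ValueError):
            pl.qualitative_fitness(u, empty)


class TestBehaviourDistance:
    def _series(self, **cols):
        species = tuple(cols)
        values = np.array([cols[s] for s in species], dtype=float)
        return pl.TimeSeries(species=species, t0=0.0, dt=1.0, values=values)

    def test_identical_series_distance_zero(self):
        a = self._series(X=[1, 2, 3])
        assert pl.behaviour_distance(a, a).d == 0.0

    def test_three_four_five(self):
        a = self._series(X=[0.0, 0.0])
        b = self._series(X=[3.0, 4.0])
        assert pl.behaviour_distance(a, b).d == pytest.approx(5.0)

    def test_mean_over_species(self):
        a = self._series(X=[0, 0], Y=[0, 0])
        b = self._series(X=[3, 4], Y=[3, 0])
        res = pl.behaviour_distance(a, b)
        assert res.eta == 2
        assert res.d == pytest.approx((5 + 3) / 2)

    def test_subset_restricts_eta(self):
        a = self._series(X=[0, 0], Y=[0, 0])
        b = self._series(X=[3, 4], Y=[3, 0])
        res = pl.behaviour_distance(a, b, subset={"Y"})
        assert res.eta == 1 and res.d == pytest.approx(3.0)

    def test_no_shared_species_errors(self):
        with pytest.raises(ValueError):
            pl.behaviour_distance(self._series(X=[1, 2]), self._series(Y=[1, 2]))

    def test_unequal_length_errors(self):
        with pytest.raises(ValueError):
            pl.behaviour_distance(self._series(X=[1, 2]),
                                  self._series(X=[1, 2, 3]))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=3),
           st.lists(st.floats(-10, 10), min_size=3, max_size=3),
           st.lists(st.floats(-10, 10), min_size=3, max_size=3))
    def test_metric_axioms(self, xs, ys, zs):
        a, b, c = (self._series(X=v) for v in (xs, ys, zs))
        dab = pl.behaviour_distance(a, b).d
        dba = pl.behaviour_distance(b, a).d
        dac = pl.behaviour_distance(a, c).d
        dcb = pl.behaviour_distance(c, b).d
        assert dab == pytest.approx(dba)
        assert dab <= dac + dcb + 1e-9
        assert pl.behaviour_distance(a, a).d == 0.0

    def test_distance_scales_linearly(self):
        a = self._series(X=[0.0, 0.0, 0.0])
        b = self._series(X=[1.0, 2.0, 2.0])
        base = pl.behaviour_distance(a, b).d
        scaled = self._series(X=[3.0, 6.0, 6.0])
        assert pl.behaviour_distance(a, scaled).d == pytest.approx(3 * base)


class TestInteractionCoverage:
    def test_self_coverage_is_one(self, rkip_bundle):
        assert pl.interaction_coverage(rkip_bundle.model, rkip_bundle.model) == 1.0

    def test_empty_candidate_covers_nothing(self, rkip_bundle):
        assert pl.interaction_coverage(pl.PetriNetModel(), rkip_bundle.model) == 0.0

    def test_two_known_reactions_cover_two_elevenths(self, rkip_bundle):
        m = pl.model_from_components([
            pl.make_binding_component("RKIP", "Raf1", 1.0),
            pl.make_binding_component("ERK", "MEKPP", 1.0)])
        cov = pl.interaction_coverage(m, rkip_bundle.model)
        assert cov == pytest.approx(2 / 11)

    def test_empty_target_errors(self, rkip_bundle):
        with pytest.raises(ValueError):
            pl.interaction_coverage(rkip_bundle.model, pl.PetriNetModel())
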