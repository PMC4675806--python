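"""(1+1)-ES structure search: seeding, mutation schedule, selection,
promotion and frequency reporting."""

import numpy as np
import pytest

import petrilearn as pl
from petrilearn.es import ESConfig, evaluate_model, mutate_structure


@pytest.fixture
def toy_cfg(toy_bundle):
    return ESConfig(rng_seed=7,
                    comparison_variables=tuple(toy_bundle.qs_t.variables))


class TestSeeding:
    def test_seeds_are_single_component_models(self, toy_library, toy_cfg):
        rng = np.random.default_rng(0)
        seeds = pl.init_seeds(toy_library, toy_cfg, rng)
        assert len(seeds) == toy_cfg.n_seeds == 20
        lib_signatures = {c.transition.signature for c in toy_library}
        for m in seeds:
            assert len(m.transitions) == 1
            assert m.transitions[0].signature in lib_signatures

    def test_seeding_is_reproducible(self, toy_library, toy_cfg):
        a = pl.init_seeds(toy_library, toy_cfg, np.random.default_rng(5))
        b = pl.init_seeds(toy_library, toy_cfg, np.random.default_rng(5))
        assert a == b

    def test_empty_library_errors(self, toy_cfg):
        with pytest.raises(ValueError):
            pl.init_seeds([], toy_cfg, np.random.default_rng(0))


class TestMutation:
    def test_addition_every_generation(self, toy_library):
        rng = np.random.default_rng(1)
        m = pl.add_component(pl.PetriNetModel(), toy_library[0])
        out = mutate_structure(m, 1, toy_library, rng)
        # either grew by one or drew the duplicate of its single component
        assert len(out.transitions) in (1, 2)
        assert any("add" in h for h in out.history[len(m.history):])

    def test_subtraction_every_second_generation(self, toy_library):
        rng = np.random.default_rng(2)
        m = pl.model_from_components(toy_library)
        out = mutate_structure(m, 2, toy_library, rng)
        ops = out.history[len(m.history):]
        assert any(h.startswith("add") for h in ops)
        assert any(h.startswith("subtract") for h in ops)
        assert len(out.transitions) - len(m.transitions) in (-1, 0, 1)

    def test_mutation_trace_is_deterministic(self, toy_library):
        m = pl.model_from_components(toy_library[:1])
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            x = m
            for g in range(1, 11):
                x = mutate_structure(x, g, toy_library, rng)
            outs.append(sorted(t.signature for t in x.transitions))
        assert outs[0] == outs[1]


class TestSelection:
    def test_offspring_without_comparison_variables_is_rejected(self, toy_bundle):
        comparison = toy_bundle.qs_t.variables
        parent = pl.model_from_components([pl.make_binding_component("A", "E", 1.0)])
        stranger = pl.model_from_components([pl.make_binding_component("X", "Y", 1.0)])
        survivor, fit, accepted = pl.step_select(parent, stranger,
                                                 toy_bundle.qs_t, comparison)
        assert survivor is parent and not accepted

    def test_equal_fitness_prefers_offspring(self, toy_bundle):
        comparison = toy_bundle.qs_t.variables
        parent = pl.model_from_components([pl.make_binding_component("A", "E", 1.0)])
        clone = parent.copy()
        survivor, _, accepted = pl.step_select(parent, clone,
                                               toy_bundle.qs_t, comparison)
        assert survivor is clone and accepted

    def test_better_coverage_wins(self, toy_bundle):
        comparison = toy_bundle.qs_t.variables
        partial = pl.model_from_components([pl.make_binding_component("A", "E", 1.0)])
        full = toy_bundle.model
        f_partial = evaluate_model(partial, toy_bundle.qs_t, comparison)
        f_full = evaluate_model(full, toy_bundle.qs_t, comparison)
        assert f_full.f1 == 1.0 > f_partial.f1
        survivor, _, accepted = pl.step_select(partial, full,
                                               toy_bundle.qs_t, comparison)
        assert survivor is full and accepted


class TestRunES:
    def test_archives_are_deterministic_under_fixed_seed(self, toy_library, toy_bundle):
        cfg = ESConfig(generations=30, n_seeds=5, rng_seed=11,
                       comparison_variables=tuple(toy_bundle.qs_t.variables))
        a = pl.run_es(toy_library, toy_bundle.qs_t, cfg)
        b = pl.run_es(toy_library, toy_bundle.qs_t, cfg)
        assert a.records == b.records

    def test_elitism_best_F_never_decreases(self, toy_library, toy_bundle):
        cfg = ESConfig(generations=40, n_seeds=6, rng_seed=3,
                       comparison_variables=tuple(toy_bundle.qs_t.variables))
        archive = pl.run_es(toy_library, toy_bundle.qs_t, cfg)
        for s in range(cfg.n_seeds):
            best = -np.inf
            for r in archive.records:
                if r.seed_index != s or not r.accepted:
                    continue
                assert r.F >= best - 1e-12
                best = max(best, r.F)

    def test_promotion_only_on_full_target_coverage(self, toy_library, toy_bundle):
        cfg = ESConfig(generations=50, n_seeds=8, rng_seed=19,
                       comparison_variables=tuple(toy_bundle.qs_t.variables))
        archive = pl.run_es(toy_library, toy_bundle.qs_t, cfg)
        promoted_records = [r for r in archive.records if r.promoted]
        assert promoted_records
        assert all(r.f1 == 1.0 for r in promoted_records)

    def test_coverage_criterion_requires_target_model(self, toy_library, toy_bundle):
        cfg = ESConfig(generations=20, n_seeds=4, rng_seed=2,
                       coverage_threshold=0.3,
                       comparison_variables=tuple(toy_bundle.qs_t.variables))
        archive = pl.run_es(toy_library, toy_bundle.qs_t, cfg,
                            target_model=toy_bundle.model)
        for r in archive.records:
            if r.promoted:
                assert r.f1 == 1.0 or (r.coverage or 0) >= 0.3

    def test_record_count_bounded(self, toy_library, toy_bundle):
        cfg = ESConfig(generations=25, n_seeds=5, rng_seed=1,
                       comparison_variables=tuple(toy_bundle.qs_t.variables))
        archive = pl.run_es(toy_library, toy_bundle.qs_t, cfg)
        assert len(archive.records) <= cfg.n_seeds * (cfg.generations + 1)


class TestComponentFrequencies:
    def test_counts_over_accepted_models(self, toy_library, toy_bundle):
        cfg = ESConfig(generations=30, n_seeds=5, rng_seed=13,
                       comparison_variables=tuple(toy_bundle.qs_t.variables))
        archive = pl.run_es(toy_library, toy_bundle.qs_t, cfg)
        freqs = pl.component_frequencies(archive, toy_bundle.model)
        counts = [c for _, c, _ in freqs]
        assert counts == sorted(counts)  # ascending, as in the report format
        accepted_total = sum(1 for r in archive.records if r.accepted)
        assert all(1 <= c <= accepted_total for c in counts)
        # every toy-library reaction that appears is flagged as a target member
        target_reactions = {t.reaction_string()
                            for t in toy_bundle.model.transitions}
        for reaction, _, member in freqs:
            assert member == (reaction in target_reactions)

    def test_empty_archive_errors(self):
        with pytest.raises(ValueError):
            pl.component_frequencies(pl.RunArchive())
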