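"""(1+1) evolution-strategy search over Petri-net model structures.

A population of independent single-parent chains is seeded with one random
library component each.  Every generation an offspring is produced by adding
one uniformly drawn library component, and additionally (on a fixed period,
default every second generation) subtracting one uniformly drawn existing
transition.  The offspring replaces the parent when its qualitative fitness F
is at least the parent's; offspring containing none of the comparison
variables are discarded outright.

A chain is *promoted* to quantitative rate fitting when it covers every
target qualitative state (f1 == 1) or, when the target topology is known,
when its interaction coverage reaches a threshold (default 80 %).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .petri import Component, PetriNetModel, add_component, subtract_component
from .qualitative import StateSet, generate_states, model_to_qde, pad_state_set, universe_size
from .fitness import FitnessResult, interaction_coverage, qualitative_fitness

__all__ = ["ESConfig", "EvalRecord", "RunArchive", "init_seeds",
           "mutate_structure", "evaluate_model", "step_select", "run_es",
           "component_frequencies"]


@dataclass
class ESConfig:
    """Search settings; defaults follow the small-scale study design
    (100 generations, 20 seeds, add every generation, subtract every two)."""

    generations: int = 100
    n_seeds: int = 20
    addition_period: int = 1
    subtraction_period: int = 2
    coverage_threshold: float = 0.8
    comparison_variables: tuple[str, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.addition_period < 1 or self.subtraction_period < 1:
            raise ValueError("mutation periods must be >= 1")
        if not (0 < self.coverage_threshold <= 1):
            raise ValueError("coverage threshold must be in (0, 1]")
        self.comparison_variables = tuple(self.comparison_variables)


@dataclass(frozen=True)
class EvalRecord:
    seed_index: int
    generation: int
    reactions: tuple[str, ...]   # canonical reaction strings of the evaluated model
    f1: float | None             # None when the offspring was discarded unevaluated
    f2: float | None
    F: float | None
    accepted: bool
    discarded: bool
    promoted: bool
    coverage: float | None = None


@dataclass
class RunArchive:
    """Every evaluation of every chain, plus the models that met a switching
    criterion (candidates for rate optimisation)."""

    records: list[EvalRecord] = field(default_factory=list)
    promoted_models: dict[int, PetriNetModel] = field(default_factory=dict)
    final_models: dict[int, PetriNetModel] = field(default_factory=dict)

    def best_per_seed(self) -> dict[int, float]:
        best: dict[int, float] = {}
        for r in self.records:
            if r.accepted:
                best[r.seed_index] = max(best.get(r.seed_index, -np.inf), r.F)
        return best


def init_seeds(library: Sequence[Component], config: ESConfig,
               rng: np.random.Generator) -> list[PetriNetModel]:
    """One single-component model per seed, drawn uniformly with replacement."""
    if not library:
        raise ValueError("component library is empty")
    seeds = []
    for _ in range(config.n_seeds):
        comp = library[rng.integers(len(library))]
        seeds.append(add_component(PetriNetModel(), comp))
    return seeds


def mutate_structure(model: PetriNetModel, generation: int,
                     library: Sequence[Component],
                     rng: np.random.Generator,
                     addition_period: int = 1,
                     subtraction_period: int = 2) -> PetriNetModel:
    """Apply the scheduled addition/subtraction operators for a generation.

    Addition first, then subtraction; subtraction on an empty model is a
    no-op.  Generations count from 1.
    """
    if generation < 1:
        raise ValueError("generations count from 1")
    out = model
    if generation % addition_period == 0:
        comp = library[rng.integers(len(library))]
        out = add_component(out, comp)
    if generation % subtraction_period == 0 and out.transitions:
        idx = int(rng.integers(len(out.transitions)))
        out = subtract_component(out, idx)
    return out


def evaluate_model(model: PetriNetModel, qs_t: StateSet,
                   comparison_variables: Sequence[str]) -> FitnessResult | None:
    """Qualitative fitness of a model on the comparison-variable vector.

    Returns None when the model contains none of the comparison variables
    (the discard rule).  Comparison variables absent from the model are
    padded with (zer, zer) — an absent species has zero concentration and
    no dynamics.
    """
    comparison_variables = tuple(comparison_variables)
    present = [v for v in comparison_variables if model.has_species(v)]
    if not present:
        return None
    qde = model_to_qde(model)
    local = tuple(v for v in qde.variables if v in set(present))
    qs_g = generate_states(qde, project_onto=local)
    qs_g = pad_state_set(qs_g, comparison_variables)
    return qualitative_fitness(qs_g, qs_t,
                               universe_size(len(comparison_variables)))


def step_select(parent: PetriNetModel, offspring: PetriNetModel,
                qs_t: StateSet, comparison_variables: Sequence[str],
                parent_fitness: FitnessResult | None = None,
                ) -> tuple[PetriNetModel, FitnessResult, bool]:
    """(1+1) survivor selection with a >= tie-break favouring the offspring.

    Returns (survivor, survivor fitness, offspring_accepted).
    """
    if parent_fitness is None:
        parent_fitness = evaluate_model(parent, qs_t, comparison_variables)
        if parent_fitness is None:
            raise ValueError("parent violates the comparison-variable rule")
    off_fitness = evaluate_model(offspring, qs_t, comparison_variables)
    if off_fitness is None:
        return parent, parent_fitness, False
    if off_fitness.F >= parent_fitness.F:
        return offspring, off_fitness, True
    return parent, parent_fitness, False


def run_es(library: Sequence[Component], qs_t: StateSet, config: ESConfig,
           rng: np.random.Generator | None = None,
           target_model: PetriNetModel | None = None) -> RunArchive:
    """Run independent (1+1) chains; promote on f1 == 1 or, when the target
    topology is supplied, on interaction coverage >= the threshold.

    A promoted chain stops evolving (it switches to rate optimisation).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    comparison = config.comparison_variables or qs_t.variables
    archive = RunArchive()
    seeds = init_seeds(library, config, rng)

    for s, parent in enumerate(seeds):
        fit = evaluate_model(parent, qs_t, comparison)
        # re-draw seeds that contain no comparison variable
        while fit is None:
            parent = init_seeds(library, ESConfig(
                generations=1, n_seeds=1,
                comparison_variables=tuple(comparison)), rng)[0]
            fit = evaluate_model(parent, qs_t, comparison)
        cov = _coverage(parent, target_model)
        promoted = _is_promoted(fit, cov, config)
        archive.records.append(_record(s, 0, parent, fit, True, False,
                                       promoted, cov))
        if promoted:
            archive.promoted_models[s] = parent
            archive.final_models[s] = parent
            continue
        for g in range(1, config.generations + 1):
            offspring = mutate_structure(
                parent.copy(), g, library, rng,
                config.addition_period, config.subtraction_period)
            off_fit = evaluate_model(offspring, qs_t, comparison)
            if off_fit is None:
                archive.records.append(_record(s, g, offspring, None, False,
                                               True, False, None))
                continue
            accepted = off_fit.F >= fit.F
            if accepted:
                parent, fit = offspring, off_fit
            cov = _coverage(parent, target_model) if accepted else None
            promoted = accepted and _is_promoted(fit, cov, config)
            archive.records.append(_record(s, g, offspring, off_fit, accepted,
                                           False, promoted, cov))
            if promoted:
                archive.promoted_models[s] = parent
                break
        archive.final_models[s] = parent
    return archive


def _coverage(model: PetriNetModel,
              target_model: PetriNetModel | None) -> float | None:
    if target_model is None or not target_model.transitions:
        return None
    return interaction_coverage(model, target_model)


def _is_promoted(fit: FitnessResult, coverage: float | None,
                 config: ESConfig) -> bool:
    if fit.f1 == 1.0:
        return True
    return coverage is not None and coverage >= config.coverage_threshold


def _record(seed: int, gen: int, model: PetriNetModel,
            fit: FitnessResult | None, accepted: bool, discarded: bool,
            promoted: bool, coverage: float | None) -> EvalRecord:
    return EvalRecord(
        seed_index=seed, generation=gen,
        reactions=tuple(sorted(t.reaction_string() for t in model.transitions)),
        f1=fit.f1 if fit else None,
        f2=fit.f2 if fit else None,
        F=fit.F if fit else None,
        accepted=accepted, discarded=discarded, promoted=promoted,
        coverage=coverage,
    )


def component_frequencies(archive: RunArchive,
                          target_model: PetriNetModel | None = None,
                          ) -> list[tuple[str, int, bool | None]]:
    """Occurrence counts of canonical reactions over all accepted models.

    Sorted ascending by count with lexicographic tie-break; each entry is
    annotated with membership in the target topology when one is supplied.
    """
    if not archive.records:
        raise ValueError("archive is empty")
    counts: Counter = Counter()
    for r in archive.records:
        if r.accepted:
            counts.update(set(r.reactions))
    target_reactions = None
    if target_model is not None:
        target_reactions = {t.reaction_string() for t in target_model.transitions}
    out = []
    for reaction, count in sorted(counts.items(), key=lambda kv: (kv[1], kv[0])):
        member = None if target_reactions is None else reaction in target_reactions
        out.append((reaction, count, member))
    return out
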