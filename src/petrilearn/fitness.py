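"""Model-selection fitness: qualitative state coverage and behaviour distance.

Qualitative fitness compares the state set a candidate model generates (QS_G)
against the target states (QS_T) and the universe of all possible states
(QS_C):

    f1 = |QS_G ∩ QS_T| / |QS_T|       (coverage — higher is better)
    f2 = |QS_G ∩ QS_C| / |QS_C|       (spuriousness — lower is better)
    F  = 1 - 1 / (1 + f1 + 1/(1 + f2))

Since the generator only produces states inside the universe, QS_G ⊆ QS_C and
f2 reduces to |QS_G| / |QS_C|; the universe therefore never needs to be
materialised, only counted.  F is strictly increasing in f1 and strictly
decreasing in f2; with f1, f2 in [0, 1] its attainable range is [1/3, 2/3].

Quantitative fitness is the mean per-species Euclidean distance between two
time series over their shared species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .petri import PetriNetModel
from .qualitative import StateSet, universe_size
from .quantitative import TimeSeries

__all__ = ["FitnessResult", "DistanceResult", "qualitative_fitness",
           "behaviour_distance", "interaction_coverage", "fitness_F"]


@dataclass(frozen=True)
class FitnessResult:
    f1: float
    f2: float
    F: float
    n_generated: int
    n_target: int
    n_universe: int
    n_overlap_target: int

    def __str__(self) -> str:
        return f"f1={self.f1:.6g} f2={self.f2:.6g} F={self.F:.6g}"


@dataclass(frozen=True)
class DistanceResult:
    d: float
    eta: int
    per_species: dict[str, float]

    def __str__(self) -> str:
        return f"d={self.d:.6g} eta={self.eta}"


def fitness_F(f1: float, f2: float) -> float:
    return 1.0 - 1.0 / (1.0 + f1 + 1.0 / (1.0 + f2))


def qualitative_fitness(qs_g: StateSet, qs_t: StateSet,
                        qs_c: StateSet | int | None = None) -> FitnessResult:
    """Score a generated state set against target states and the universe.

    ``qs_c`` may be a materialised universe, its size, or None (defaults to
    6**n over the shared variable vector).
    """
    if qs_g.variables != qs_t.variables:
        raise ValueError(
            f"variable vectors differ: {qs_g.variables} vs {qs_t.variables}"
        )
    if len(qs_t) == 0:
        raise ValueError("target state set must be non-empty")
    if qs_c is None:
        n_universe = universe_size(len(qs_g.variables))
    elif isinstance(qs_c, int):
        n_universe = qs_c
    else:
        if qs_c.variables != qs_g.variables:
            raise ValueError("universe variable vector differs")
        n_universe = len(qs_c)
    if n_universe == 0:
        raise ValueError("universe must be non-empty")
    overlap = qs_g.intersection_size(qs_t)
    f1 = overlap / len(qs_t)
    f2 = len(qs_g) / n_universe  # QS_G ⊆ QS_C by construction
    return FitnessResult(f1=f1, f2=f2, F=fitness_F(f1, f2),
                         n_generated=len(qs_g), n_target=len(qs_t),
                         n_universe=n_universe, n_overlap_target=overlap)


def behaviour_distance(target: TimeSeries, candidate: TimeSeries,
                       subset: set[str] | None = None) -> DistanceResult:
    """Mean per-species Euclidean distance over the shared species.

    ``subset`` restricts the comparison to named species (the distance is
    then averaged over those alone).
    """
    shared = [s for s in target.species if s in candidate.species]
    if subset is not None:
        shared = [s for s in shared if s in subset]
    if not shared:
        raise ValueError("no shared species to compare")
    if target.n_points != candidate.n_points:
        raise ValueError(
            f"series length differs: {target.n_points} vs {candidate.n_points}"
        )
    per = {}
    for s in shared:
        diff = target.get(s) - candidate.get(s)
        per[s] = float(np.sqrt(np.sum(diff * diff)))
    eta = len(shared)
    return DistanceResult(d=sum(per.values()) / eta, eta=eta, per_species=per)


def interaction_coverage(candidate: PetriNetModel,
                         target: PetriNetModel) -> float:
    """Fraction of the target's reactions present in the candidate.

    Reactions match on canonicalised input/output multisets, so complexes
    written with their constituents in any order compare equal.
    """
    if not target.transitions:
        raise ValueError("target model has no transitions")
    cand = candidate.transition_signatures()
    hits = sum(1 for t in target.transitions if t.signature in cand)
    return hits / len(target.transitions)
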