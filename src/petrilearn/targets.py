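"""Packaged target systems and synthetic target-bundle generation.

Ships two reference topologies — a three-reaction enzymatic toy and the
RKIP-regulated ERK signalling pathway — together with the reference
qualitative-state table and the component-frequency table used by the
structure-search reports.  ``make_target_bundle`` turns any model into a
learning target: simulate its mass-action ODEs, abstract the trajectories to
qualitative states, and package everything with full provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .petri import (PetriNetModel, Transition, decompose_enzymatic,
                    model_from_components)
from .qualitative import StateSet, abstract_states, generate_states, model_to_qde
from .quantitative import TimeSeries, model_to_odes, simulate
from .io import parse_model_text, parse_state_tsv, _parse_side

__all__ = ["TargetBundle", "FixtureChecksumError", "toy_enzymatic_target",
           "rkip_target", "table1_states", "table2_components",
           "target_membership_count", "make_target_bundle",
           "RKIP_OBSERVED_SPECIES"]

_CHECKSUMS = {
    "table1_states.tsv":
        "39a4a30b4435bc3fcb202c5168ca5c992189c43522f3f78b97b5d9975bcde855",
    "table2_components.tsv":
        "bcdc46d88a4d963b7b3bb8c319587db48bad849b4c9b7cb276af80aa57f646a6",
    "rkip_pathway.model":
        "aee916aac6f88cf4b2a46a264f3ec03ffb092c8bc19ad1f3bd7a41f1706559dc",
}

# The eight species whose behaviours the case study compares.
RKIP_OBSERVED_SPECIES = ("Raf1", "RKIP", "RKIPP", "ERK", "RP", "MEKPP",
                     "RKIP|Raf1", "ERK|MEKPP")


class FixtureChecksumError(RuntimeError):
    """A packaged fixture file does not match its recorded checksum."""


def _load_fixture(name: str) -> str:
    text = resources.files("petrilearn.data").joinpath(name).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureChecksumError(f"{name}: checksum mismatch ({digest})")
    return text


@dataclass
class TargetBundle:
    """A learning target: optional true topology, target qualitative states,
    target time series, and the parameters that produced them."""

    qs_t: StateSet
    series: TimeSeries
    model: PetriNetModel | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model is not None:
            places = set(self.model.place_labels())
            for v in set(self.qs_t.variables) | set(self.series.species):
                if v not in places:
                    raise ValueError(f"target variable {v!r} not in model places")


def toy_enzymatic_target(k1: float = 1.0, k2: float = 0.5, k3: float = 0.8,
                         a0: float = 4.0, e0: float = 5.0,
                         t_end: float = 10.0, P: int = 100) -> TargetBundle:
    """The enzymatic toy system A + E <-> A|E -> AP + E.

    Defaults (k = 1.0/0.5/0.8, A0 = 4, E0 = 5, 100 samples over 10 time
    units) are the package's documented reference conditions.  Target
    qualitative states are all states the toy's own sign constraints admit
    over its four species.
    """
    comps = decompose_enzymatic("A", "E", (k1, k2, k3))
    model = model_from_components(comps, initial={"A": a0, "E": e0})
    series = simulate(model_to_odes(model), model.initial_concentrations(),
                      t_end=t_end, P=P)
    qs_t = generate_states(model_to_qde(model))
    qs_t.role = "QS_T"
    return TargetBundle(
        qs_t=qs_t, series=series, model=model,
        provenance={"system": "toy_enzymatic",
                    "rates": {"k1": k1, "k2": k2, "k3": k3},
                    "initial": {"A": a0, "E": e0},
                    "t_end": t_end, "P": P,
                    "qs_t": "all consistent states of the true topology"},
    )


def rkip_target(t_end: float = 50.0, P: int = 100) -> TargetBundle:
    """The RKIP/ERK signalling pathway target (11 species, 11 reactions).

    Target qualitative states over the eight compared species are abstracted
    from the simulated trajectories, mirroring how the case-study target
    states were obtained from a quantitative simulator.
    """
    model = parse_model_text(_load_fixture("rkip_pathway.model"),
                             name="rkip_pathway.model")
    series = simulate(model_to_odes(model), model.initial_concentrations(),
                      t_end=t_end, P=P)
    observed = series.restrict(RKIP_OBSERVED_SPECIES)
    qs_t = abstract_states(observed)
    qs_t.role = "QS_T"
    return TargetBundle(
        qs_t=qs_t, series=observed, model=model,
        provenance={"system": "rkip_pathway",
                    "source": "packaged fixture (synthetic literature values)",
                    "t_end": t_end, "P": P,
                    "qs_t": "abstracted from simulated trajectories"},
    )


def table1_states() -> StateSet:
    """The 14 reference qualitative states over {A, AP, B, BP}."""
    ss = parse_state_tsv(_load_fixture("table1_states.tsv"))
    ss.role = "QS_T"
    return ss


def table2_components() -> list[tuple[Transition, int, bool]]:
    """The 11 most frequently explored components of the case study, with
    their frequencies and target-membership flags."""
    rows = []
    text = _load_fixture("table2_components.tsv")
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        _, reaction, freq, flag = line.split("\t")
        lhs, rhs = reaction.split("->")
        t = Transition(id=reaction.strip(),
                       inputs=_parse_side(lhs, 0), outputs=_parse_side(rhs, 0),
                       rate_constant=1.0)
        rows.append((t, int(freq), flag.strip() == "Yes"))
    return rows


def target_membership_count(components, target: PetriNetModel) -> int:
    """How many of the given reactions appear in the target topology.

    ``components`` is an iterable of Transitions, Components, or
    (Transition, ...) rows as returned by :func:`table2_components`; matching
    is by canonical input/output multisets.
    """
    signatures = target.transition_signatures()
    count = 0
    for item in components:
        t = item
        if isinstance(item, tuple):
            t = item[0]
        if hasattr(t, "transition"):
            t = t.transition
        if t.signature in signatures:
            count += 1
    return count


def make_target_bundle(model: PetriNetModel, t_end: float, P: int = 100,
                       observed_species: tuple[str, ...] | None = None,
                       eps_mag: float | None = None,
                       eps_der: float | None = None,
                       rng_seed: int | None = None) -> TargetBundle:
    """Generic synthetic-target generator: simulate, abstract, package."""
    series = simulate(model_to_odes(model), model.initial_concentrations(),
                      t_end=t_end, P=P)
    if observed_species is not None:
        series = series.restrict(observed_species)
    qs_t = abstract_states(series, eps_mag=eps_mag, eps_der=eps_der)
    qs_t.role = "QS_T"
    return TargetBundle(
        qs_t=qs_t, series=series, model=model,
        provenance={"system": "synthetic",
                    "reactions": [t.reaction_string() for t in model.transitions],
                    "rates": [t.rate_constant for t in model.transitions],
                    "initial": model.initial_concentrations(),
                    "t_end": t_end, "P": P,
                    "eps_mag": eps_mag, "eps_der": eps_der,
                    "rng_seed": rng_seed},
    )
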