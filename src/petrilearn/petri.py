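"""Petri-net model representation and the component algebra.

Biochemical models are continuous Petri nets: places hold species
concentrations, transitions are reactions with mass-action rate constants.
Models are grown from *components* — atomic one-transition nets instantiated
from two patterns:

* binding:    substrate + enzyme -> substrate|enzyme
* unbinding:  complex -> its two constituents (reverse), or
              complex -> phosphorylated substrate + enzyme (convert)

Components compose by merging places with the same species identity.
Complex species identity is the multiset of constituent labels, so
``RKIP|Raf1`` and ``Raf1|RKIP`` are the same place; the canonical label
joins the constituents sorted lexicographically with ``|``.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

__all__ = [
    "Species",
    "Transition",
    "Component",
    "PetriNetModel",
    "make_binding_component",
    "make_unbinding_component",
    "decompose_enzymatic",
    "build_component_library",
    "add_component",
    "subtract_component",
    "model_from_components",
    "validate_model",
    "canonical_label",
    "species_key",
    "InvalidParameterError",
    "PatternError",
    "ModelInvariantError",
]

_LABEL_RE = re.compile(r"^[A-Za-z0-9_*]+$")

Kind = Literal["primitive", "complex", "product"]
PatternName = Literal["binding", "unbinding_reverse", "unbinding_convert"]


class InvalidParameterError(ValueError):
    """A numeric parameter violates its domain (e.g. non-positive rate)."""


class PatternError(ValueError):
    """A species does not fit the requested component pattern."""


class ModelInvariantError(ValueError):
    """A model violates a structural invariant."""


def _check_label(label: str) -> None:
    if not label:
        raise InvalidParameterError("species label must be non-empty")
    for part in label.split("|"):
        if not _LABEL_RE.match(part):
            raise InvalidParameterError(f"malformed species label: {label!r}")


def canonical_label(label: str) -> str:
    """Canonical form of a species label: complex constituents sorted."""
    if "|" in label:
        return "|".join(sorted(label.split("|")))
    return label


def species_key(label: str) -> tuple[str, ...]:
    """Identity key of a species: the sorted constituent multiset.

    Complexes compare equal regardless of the order the constituents are
    written in; simple species compare by label.
    """
    return tuple(sorted(label.split("|")))


@dataclass(frozen=True)
class Species:
    """A molecular species occupying one Petri-net place.

    ``constituents`` is the ordered list of parts for a complex (length >= 2)
    and empty otherwise.  ``label`` is always canonical (sorted constituents
    joined by ``|``); the construction order of the constituents is preserved
    separately because the convert unbinding pattern phosphorylates the
    *first* constituent.
    """

    label: str
    kind: Kind = "primitive"
    constituents: tuple[str, ...] = ()
    initial_concentration: float = 0.0

    def __post_init__(self) -> None:
        _check_label(self.label)
        if self.initial_concentration < 0:
            raise InvalidParameterError(
                f"initial concentration of {self.label} must be >= 0"
            )
        if "|" in self.label:
            object.__setattr__(self, "kind", "complex")
            if not self.constituents:
                object.__setattr__(
                    self, "constituents", tuple(self.label.split("|"))
                )
            object.__setattr__(self, "label", canonical_label(self.label))
        elif self.constituents:
            raise ModelInvariantError(
                f"simple species {self.label} must not list constituents"
            )

    @property
    def key(self) -> tuple[str, ...]:
        return species_key(self.label)

    @staticmethod
    def make(label: str, initial_concentration: float = 0.0,
             kind: Kind | None = None) -> "Species":
        if kind is None:
            kind = "complex" if "|" in label else "primitive"
        return Species(label=label, kind=kind,
                       initial_concentration=initial_concentration)

    @staticmethod
    def complex_of(*parts: str, initial_concentration: float = 0.0) -> "Species":
        if len(parts) < 2:
            raise PatternError("a complex needs at least two constituents")
        return Species(
            label="|".join(sorted(parts)),
            kind="complex",
            constituents=tuple(parts),
            initial_concentration=initial_concentration,
        )


def _canon_multiset(ms: Counter) -> tuple[tuple[tuple[str, ...], int], ...]:
    return tuple(sorted((species_key(lbl), c) for lbl, c in ms.items()))


@dataclass(frozen=True)
class Transition:
    """A reaction: input and output species multisets plus a rate constant."""

    id: str
    inputs: tuple[tuple[str, int], ...]   # (species label, coefficient)
    outputs: tuple[tuple[str, int], ...]
    rate_constant: float

    def __post_init__(self) -> None:
        if self.rate_constant <= 0:
            raise InvalidParameterError(
                f"rate constant of {self.id} must be > 0"
            )
        ins = {species_key(l) for l, _ in self.inputs}
        outs = {species_key(l) for l, _ in self.outputs}
        if ins & outs:
            raise ModelInvariantError(
                f"{self.id}: a species appears on both sides"
            )
        for _, c in self.inputs + self.outputs:
            if c < 1:
                raise ModelInvariantError(
                    f"{self.id}: stoichiometric coefficients must be >= 1"
                )

    @property
    def input_multiset(self) -> Counter:
        return Counter({canonical_label(l): c for l, c in self.inputs})

    @property
    def output_multiset(self) -> Counter:
        return Counter({canonical_label(l): c for l, c in self.outputs})

    @property
    def signature(self) -> tuple:
        """Structural identity: canonical input/output multisets (rate ignored)."""
        return (_canon_multiset(self.input_multiset),
                _canon_multiset(self.output_multiset))

    def reaction_string(self) -> str:
        def side(pairs: Counter) -> str:
            return " + ".join(
                (f"{c} {l}" if c > 1 else l) for l, c in sorted(pairs.items())
            )
        return f"{side(self.input_multiset)} -> {side(self.output_multiset)}"


@dataclass(frozen=True)
class Component:
    """An atomic one-transition Petri net; the unit of structural mutation."""

    transition: Transition
    pattern: PatternName
    species: tuple[Species, ...]

    def reaction_string(self) -> str:
        return self.transition.reaction_string()


@dataclass
class PetriNetModel:
    """A composed model: places keyed by species identity, ordered transitions.

    ``history`` logs the operator applications that produced the model, for
    reporting and replay.
    """

    places: dict[tuple[str, ...], Species] = field(default_factory=dict)
    transitions: list[Transition] = field(default_factory=list)
    history: list[str] = field(default_factory=list)

    def place_labels(self) -> list[str]:
        return [sp.label for sp in self.places.values()]

    def has_species(self, label: str) -> bool:
        return species_key(label) in self.places

    def transition_signatures(self) -> set[tuple]:
        return {t.signature for t in self.transitions}

    def initial_concentrations(self) -> dict[str, float]:
        return {sp.label: sp.initial_concentration for sp in self.places.values()}

    def set_initial(self, label: str, value: float) -> None:
        key = species_key(label)
        if key not in self.places:
            raise ModelInvariantError(f"unknown species {label!r}")
        self.places[key] = replace(self.places[key], initial_concentration=value)

    def copy(self) -> "PetriNetModel":
        return PetriNetModel(
            places=dict(self.places),
            transitions=list(self.transitions),
            history=list(self.history),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PetriNetModel):
            return NotImplemented
        return (
            self.places == other.places
            and Counter(t.signature for t in self.transitions)
            == Counter(t.signature for t in other.transitions)
            and [t.rate_constant for t in self.transitions]
            == [t.rate_constant for t in other.transitions]
        )


def validate_model(model: PetriNetModel) -> None:
    """Check all structural invariants; raise ModelInvariantError on failure."""
    incident: set[tuple[str, ...]] = set()
    seen_signatures: set[tuple] = set()
    for t in model.transitions:
        for lbl, _ in t.inputs + t.outputs:
            key = species_key(lbl)
            if key not in model.places:
                raise ModelInvariantError(
                    f"{t.id} references species {lbl!r} missing from places"
                )
            incident.add(key)
        if t.signature in seen_signatures:
            raise ModelInvariantError(f"duplicate transition {t.id}")
        seen_signatures.add(t.signature)
    if model.transitions:
        orphans = set(model.places) - incident
        if orphans:
            labels = sorted(model.places[k].label for k in orphans)
            raise ModelInvariantError(f"orphan places: {labels}")


# ---------------------------------------------------------------------------
# Component instantiation patterns
# ---------------------------------------------------------------------------

def make_binding_component(substrate: str, enzyme: str, k: float) -> Component:
    """Instantiate the binding pattern: substrate + enzyme -> substrate|enzyme.

    A homodimer (substrate == enzyme) binds with stoichiometry 2 on the
    single reactant.
    """
    _check_label(substrate)
    _check_label(enzyme)
    if k <= 0:
        raise InvalidParameterError("rate constant must be > 0")
    if "|" in substrate or "|" in enzyme:
        raise PatternError("binding reactants must be non-complex species")
    cplx = Species.complex_of(substrate, enzyme)
    if substrate == enzyme:
        inputs = ((substrate, 2),)
        species = (Species.make(substrate), cplx)
    else:
        inputs = ((substrate, 1), (enzyme, 1))
        species = (Species.make(substrate), Species.make(enzyme), cplx)
    t = Transition(
        id=f"bind:{substrate}+{enzyme}",
        inputs=inputs,
        outputs=((cplx.label, 1),),
        rate_constant=k,
    )
    return Component(transition=t, pattern="binding", species=species)


def make_unbinding_component(complex_label: str,
                             mode: Literal["reverse", "convert"],
                             k: float,
                             constituents: Sequence[str] | None = None,
                             ) -> Component:
    """Instantiate the unbinding pattern for a two-constituent complex.

    ``reverse`` releases the original constituents; ``convert`` releases the
    first constituent phosphorylated (label + 'P') together with the second
    (the enzyme) unchanged.  Constituent order defaults to the order written
    in ``complex_label``.
    """
    _check_label(complex_label)
    if k <= 0:
        raise InvalidParameterError("rate constant must be > 0")
    parts = tuple(constituents) if constituents else tuple(complex_label.split("|"))
    if len(parts) != 2:
        raise PatternError(
            f"unbinding needs a complex of exactly 2 constituents, got {parts}"
        )
    cplx = Species.complex_of(*parts)
    if mode == "reverse":
        a, b = parts
        out = Counter([a, b])
        outputs = tuple(out.items())
        species = tuple({p: Species.make(p) for p in parts}.values()) + (cplx,)
        pattern: PatternName = "unbinding_reverse"
        tid = f"unbind:{cplx.label}"
    elif mode == "convert":
        product = parts[0] + "P"
        enzyme = parts[1]
        out = Counter([product, enzyme])
        outputs = tuple(out.items())
        species = (cplx, Species.make(product, kind="product"),
                   Species.make(enzyme))
        pattern = "unbinding_convert"
        tid = f"convert:{cplx.label}->{product}"
    else:
        raise PatternError(f"unknown unbinding mode {mode!r}")
    t = Transition(
        id=tid,
        inputs=((cplx.label, 1),),
        outputs=outputs,
        rate_constant=k,
    )
    return Component(transition=t, pattern=pattern, species=species)


def decompose_enzymatic(substrate: str, enzyme: str,
                        k: tuple[float, float, float] = (1.0, 1.0, 1.0),
                        ) -> list[Component]:
    """The three atomic components of the enzymatic scheme
    substrate + enzyme <-> substrate|enzyme -> substrateP + enzyme."""
    k1, k2, k3 = k
    binding = make_binding_component(substrate, enzyme, k1)
    cplx = "|".join((substrate, enzyme))
    reverse = make_unbinding_component(cplx, "reverse", k2,
                                       constituents=(substrate, enzyme))
    convert = make_unbinding_component(cplx, "convert", k3,
                                       constituents=(substrate, enzyme))
    return [binding, reverse, convert]


def build_component_library(s_species: Iterable[str],
                            s_enzymes: Iterable[str],
                            default_k: float = 1.0) -> list[Component]:
    """All enzymatic triples over ordered (species, enzyme) pairs.

    Size is 3 * |S_species| * |S_enzymes|; ordering is lexicographic by pair
    then pattern (binding, reverse, convert) so libraries are deterministic.
    """
    if default_k <= 0:
        raise InvalidParameterError("default rate constant must be > 0")
    lib: list[Component] = []
    for sub in sorted(set(s_species)):
        for enz in sorted(set(s_enzymes)):
            lib.extend(decompose_enzymatic(sub, enz,
                                           (default_k, default_k, default_k)))
    return lib


# ---------------------------------------------------------------------------
# Composition operators
# ---------------------------------------------------------------------------

def add_component(model: PetriNetModel, comp: Component) -> PetriNetModel:
    """Compose a component into a model by merging shared places.

    Existing places keep their initial concentration; new places start at 0
    unless the component's species carries one.  A transition structurally
    identical to an existing one is skipped (the model is returned unchanged
    apart from a history entry).
    """
    out = model.copy()
    if comp.transition.signature in out.transition_signatures():
        out.history.append(f"add(skip-duplicate): {comp.reaction_string()}")
        return out
    for sp in comp.species:
        if sp.key not in out.places:
            out.places[sp.key] = sp
    n = len(out.transitions) + 1
    t = replace(comp.transition, id=f"T{n}")
    out.transitions.append(t)
    out.history.append(f"add: {comp.reaction_string()}")
    validate_model(out)
    return out


def subtract_component(model: PetriNetModel, index: int) -> PetriNetModel:
    """Remove the transition at ``index``; prune places left unconnected.

    Subtracting from an empty model is a logged no-op.
    """
    out = model.copy()
    if not out.transitions:
        out.history.append("subtract: no-op (empty model)")
        return out
    removed = out.transitions.pop(index)
    incident: set[tuple[str, ...]] = set()
    for t in out.transitions:
        for lbl, _ in t.inputs + t.outputs:
            incident.add(species_key(lbl))
    out.places = {k: v for k, v in out.places.items() if k in incident}
    out.history.append(f"subtract: {removed.reaction_string()}")
    validate_model(out)
    return out


def model_from_components(components: Iterable[Component],
                          initial: dict[str, float] | None = None,
                          ) -> PetriNetModel:
    """Convenience constructor: fold add_component over a component list."""
    model = PetriNetModel()
    for comp in components:
        model = add_component(model, comp)
    if initial:
        for label, value in initial.items():
            model.set_initial(label, value)
    return model
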