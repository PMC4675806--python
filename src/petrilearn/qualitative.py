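"""Sign-algebra qualitative simulation of Petri-net models.

A model is abstracted to a qualitative differential equation over the signs
quantity space: every species variable carries a magnitude in {zer, pos}
(concentrations are non-negative) and a derivative in {neg, zer, pos}.

Each transition j contributes, to the derivative of variable X, the sign
``s_ij * r_j`` where ``s_ij`` is the sign of the net stoichiometric change of
X in j and ``r_j`` is *pos* when every input of j has positive magnitude and
*zer* otherwise (mass action: a reaction only fires when all reactants are
present).  Contributions combine by qualitative summation: conflicting signs
yield the full set {neg, zer, pos}, otherwise the common sign (or zer).

The engine enumerates every qualitative state consistent with those
per-variable constraints.  Derivative co-variation between variables is
deliberately NOT enforced — this is the weakest sound semantics and
over-generates (spurious) states, which the model-selection fitness
penalises through its parsimony term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

from .petri import PetriNetModel, canonical_label

__all__ = [
    "Sign",
    "QualitativeValue",
    "QualitativeState",
    "QDEModel",
    "StateSet",
    "model_to_qde",
    "enumerate_universe",
    "universe_size",
    "generate_states",
    "abstract_states",
]

NEG, ZER, POS = "neg", "zer", "pos"
Sign = str
SIGNS = (NEG, ZER, POS)
MAGNITUDES = (ZER, POS)  # concentrations cannot be negative


@dataclass(frozen=True, order=True)
class QualitativeValue:
    """A (magnitude, derivative) sign pair for one variable."""

    magnitude: Sign
    derivative: Sign

    def __post_init__(self) -> None:
        if self.magnitude not in MAGNITUDES:
            raise ValueError(f"magnitude must be zer/pos, got {self.magnitude}")
        if self.derivative not in SIGNS:
            raise ValueError(f"derivative must be neg/zer/pos, got {self.derivative}")

    def __str__(self) -> str:
        return f"<{self.magnitude},{self.derivative}>"


class QualitativeState(tuple):
    """A complete assignment of qualitative values over a variable vector.

    Stored as a tuple of QualitativeValue aligned with the owning StateSet's
    variable vector; two states are equal iff all assignments are equal.
    """

    __slots__ = ()

    def __new__(cls, values: Iterable[QualitativeValue]):
        return super().__new__(cls, tuple(values))

    @staticmethod
    def from_mapping(variables: Sequence[str],
                     assignment: Mapping[str, QualitativeValue]
                     ) -> "QualitativeState":
        return QualitativeState(assignment[v] for v in variables)


@dataclass
class StateSet:
    """A deduplicated set of qualitative states over a common variable vector."""

    variables: tuple[str, ...]
    states: frozenset = frozenset()
    role: str = ""  # one of QS_G / QS_T / QS_C, or empty

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.states = frozenset(self.states)
        for st in self.states:
            if len(st) != len(self.variables):
                raise ValueError("state arity does not match variable vector")

    def __len__(self) -> int:
        return len(self.states)

    def __contains__(self, state: QualitativeState) -> bool:
        return state in self.states

    def __iter__(self):
        return iter(self.states)

    def intersection_size(self, other: "StateSet") -> int:
        if self.variables != other.variables:
            raise ValueError(
                f"variable vectors differ: {self.variables} vs {other.variables}"
            )
        return len(self.states & other.states)


def _sign(x: float | int) -> Sign:
    if x > 0:
        return POS
    if x < 0:
        return NEG
    return ZER


def _qualitative_sum(signs: Iterable[Sign]) -> frozenset:
    has_pos = any(s == POS for s in signs)
    has_neg = any(s == NEG for s in signs)
    if has_pos and has_neg:
        return frozenset(SIGNS)
    if has_pos:
        return frozenset({POS})
    if has_neg:
        return frozenset({NEG})
    return frozenset({ZER})


@dataclass
class QDEModel:
    """Per-variable sign constraints derived from a Petri-net structure.

    ``terms[v]`` is a list of (s_ij, inputs-of-transition-j) pairs: the
    contribution of each transition to variable v and the species whose
    positive magnitude it requires to fire.
    """

    variables: tuple[str, ...]
    terms: dict[str, list[tuple[Sign, frozenset]]] = field(default_factory=dict)

    def permitted_derivatives(self, magnitudes: Mapping[str, Sign]
                              ) -> dict[str, frozenset]:
        """Permitted-derivative set of every variable under a magnitude map."""
        out: dict[str, frozenset] = {}
        for v in self.variables:
            contributions = []
            for s_ij, inputs in self.terms.get(v, []):
                fires = all(magnitudes[u] == POS for u in inputs)
                contributions.append(s_ij if fires else ZER)
            out[v] = _qualitative_sum(contributions)
        return out

    def dependencies(self, variable: str) -> frozenset:
        """Variables whose magnitudes the constraint on ``variable`` reads."""
        deps: set[str] = set()
        for s_ij, inputs in self.terms.get(variable, []):
            if s_ij != ZER:
                deps |= inputs
        return frozenset(deps)


def model_to_qde(model: PetriNetModel) -> QDEModel:
    """Abstract a Petri-net model to its sign-constraint QDE."""
    variables = tuple(sorted(model.place_labels()))
    terms: dict[str, list[tuple[Sign, frozenset]]] = {v: [] for v in variables}
    for t in model.transitions:
        ins = t.input_multiset
        outs = t.output_multiset
        inputs = frozenset(canonical_label(l) for l in ins)
        for v in set(ins) | set(outs):
            s = _sign(outs.get(v, 0) - ins.get(v, 0))
            terms[v].append((s, inputs))
    return QDEModel(variables=variables, terms=terms)


def universe_size(n_variables: int) -> int:
    """|QS_C| for n variables: (2 magnitudes * 3 derivatives) ** n."""
    return 6 ** n_variables


def enumerate_universe(variables: Sequence[str]) -> StateSet:
    """All possible qualitative states over the variable vector (QS_C)."""
    variables = tuple(variables)
    if not variables:
        raise ValueError("need at least one variable")
    values = [QualitativeValue(m, d) for m in MAGNITUDES for d in SIGNS]
    states = frozenset(
        QualitativeState(combo) for combo in product(values, repeat=len(variables))
    )
    return StateSet(variables=variables, states=states, role="QS_C")


def generate_states(qde: QDEModel,
                    project_onto: Sequence[str] | None = None) -> StateSet:
    """All consistent qualitative states of a QDE, projected onto a sub-vector.

    Enumeration is exact but only over the *relevant* variables — the
    projection targets plus every variable their constraints read — so the
    cost is 2**|relevant| rather than 2**|all places|.
    """
    proj = tuple(project_onto) if project_onto is not None else qde.variables
    unknown = [v for v in proj if v not in qde.variables]
    if unknown:
        raise ValueError(f"unknown projection variables: {unknown}")
    if not proj:
        raise ValueError("projection vector must be non-empty")

    relevant: set[str] = set(proj)
    for v in proj:
        relevant |= qde.dependencies(v)
    relevant_vars = tuple(sorted(relevant))

    states: set[QualitativeState] = set()
    # magnitudes of variables outside `relevant` cannot influence the
    # permitted-derivative sets of the projected variables, and every
    # variable's permitted set is non-empty, so any partial state below
    # extends to a full consistent state.
    for mags in product(MAGNITUDES, repeat=len(relevant_vars)):
        mag_map = dict(zip(relevant_vars, mags))
        permitted = {v: _permitted_for(qde, v, mag_map) for v in proj}
        per_var = [
            [QualitativeValue(mag_map[v], d) for d in sorted(permitted[v])]
            for v in proj
        ]
        for combo in product(*per_var):
            states.add(QualitativeState(combo))
    return StateSet(variables=proj, states=frozenset(states), role="QS_G")


def _permitted_for(qde: QDEModel, variable: str,
                   magnitudes: Mapping[str, Sign]) -> frozenset:
    contributions = []
    for s_ij, inputs in qde.terms.get(variable, []):
        fires = all(magnitudes.get(u, ZER) == POS for u in inputs)
        contributions.append(s_ij if fires else ZER)
    return _qualitative_sum(contributions)


def abstract_states(ts, eps_mag: float | None = None,
                    eps_der: float | None = None) -> StateSet:
    """Abstract a quantitative time series into qualitative states.

    Magnitude is *zer* below ``eps_mag`` and *pos* otherwise; the derivative
    is the sign of the central finite difference, thresholded at ``eps_der``.
    Thresholds default to 1e-6 times the largest observed value.  Consecutive
    duplicate states are collapsed before deduplication.
    """
    values = ts.values  # (n_species, P) array
    if values.shape[1] < 2:
        raise ValueError("need at least two time points")
    vmax = float(np.max(values)) if values.size else 0.0
    scale = vmax if vmax > 0 else 1.0
    if eps_mag is None:
        eps_mag = 1e-6 * scale
    if eps_der is None:
        eps_der = 1e-6 * scale
    dt = ts.dt
    deriv = np.gradient(values, dt, axis=1)  # central; one-sided at the ends

    seq: list[QualitativeState] = []
    for j in range(values.shape[1]):
        vals = []
        for i in range(values.shape[0]):
            mag = ZER if values[i, j] < eps_mag else POS
            d = deriv[i, j]
            der = ZER if abs(d) < eps_der else (POS if d > 0 else NEG)
            vals.append(QualitativeValue(mag, der))
        st = QualitativeState(vals)
        if not seq or seq[-1] != st:
            seq.append(st)
    return StateSet(variables=tuple(ts.species), states=frozenset(seq))


def pad_state_set(ss: StateSet, variables: Sequence[str]) -> StateSet:
    """Extend a state set onto a wider variable vector.

    Variables absent from ``ss`` are assigned (zer, zer): a species missing
    from a model has zero concentration and no dynamics.
    """
    variables = tuple(variables)
    idx = {v: i for i, v in enumerate(ss.variables)}
    zz = QualitativeValue(ZER, ZER)
    states = frozenset(
        QualitativeState(st[idx[v]] if v in idx else zz for v in variables)
        for st in ss
    )
    return StateSet(variables=variables, states=states, role=ss.role)
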