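"""Mass-action ODE semantics of continuous Petri nets.

Each transition j fires at velocity gamma_j * prod_k X_k^{f_jk}, the kinetic
order f_jk being the input stoichiometric coefficient (mass-action kinetics).
Species dynamics follow dX_i/dt = sum_j mu_ij * v_j with mu_ij the net
stoichiometric change of X_i in transition j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import odeint

from .petri import PetriNetModel

__all__ = ["ODESystem", "TimeSeries", "IntegrationError",
           "model_to_odes", "simulate"]


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the solver's diagnostic message."""


@dataclass
class ODESystem:
    """Stoichiometric form of a model's mass-action ODEs.

    stoichiometry[i, j] = mu_ij (net change of species i in transition j);
    kinetic_orders[i, j] = f_ji (exponent of species i in the rate of j,
    equal to the input coefficient, 0 for non-reactants).
    """

    variables: tuple[str, ...]
    stoichiometry: np.ndarray   # (n_species, n_transitions) signed ints
    rates: np.ndarray           # (n_transitions,) gamma_j > 0
    kinetic_orders: np.ndarray  # (n_species, n_transitions) non-negative ints

    def velocity(self, x: np.ndarray) -> np.ndarray:
        xs = np.clip(x, 0.0, None)
        # prod_k X_k^{f_jk}, computed in log space would lose zeros; use power
        terms = xs[:, None] ** self.kinetic_orders
        return self.rates * np.prod(terms, axis=0)

    def rhs(self, _t: float, x: np.ndarray) -> np.ndarray:
        return self.stoichiometry @ self.velocity(x)

    def jacobian(self, _t: float, x: np.ndarray) -> np.ndarray:
        xs = np.clip(x, 0.0, None)
        n, m = self.kinetic_orders.shape
        terms = xs[:, None] ** self.kinetic_orders  # (n, m)
        v = self.rates * np.prod(terms, axis=0)     # (m,)
        # dv_j/dx_k = f_jk * v_j / x_k (guard x_k = 0 via one-sided limit)
        dv = np.zeros((m, n))
        for k in range(n):
            f = self.kinetic_orders[k]
            with np.errstate(divide="ignore", invalid="ignore"):
                if xs[k] > 0:
                    dv[:, k] = f * v / xs[k]
                else:
                    mask = f == 1
                    others = np.prod(np.delete(terms, k, axis=0), axis=0)
                    dv[mask, k] = self.rates[mask] * others[mask]
        return self.stoichiometry @ dv


@dataclass
class TimeSeries:
    """Concentration trajectories on a uniform time grid."""

    species: tuple[str, ...]
    t0: float
    dt: float
    values: np.ndarray  # (n_species, P)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.species):
            raise ValueError("values must be (n_species, P)")
        if self.values.shape[1] < 2:
            raise ValueError("need P >= 2 time points")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_points(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_points)

    def get(self, label: str) -> np.ndarray:
        return self.values[self.species.index(label)]

    def restrict(self, labels) -> "TimeSeries":
        idx = [self.species.index(l) for l in labels]
        return TimeSeries(species=tuple(labels), t0=self.t0, dt=self.dt,
                          values=self.values[idx])


def model_to_odes(model: PetriNetModel) -> ODESystem:
    """Build the mass-action ODE system of a model (places in sorted order)."""
    variables = tuple(sorted(model.place_labels()))
    index = {v: i for i, v in enumerate(variables)}
    n, m = len(variables), len(model.transitions)
    stoich = np.zeros((n, m), dtype=int)
    orders = np.zeros((n, m), dtype=int)
    rates = np.zeros(m)
    for j, t in enumerate(model.transitions):
        rates[j] = t.rate_constant
        for lbl, c in t.input_multiset.items():
            stoich[index[lbl], j] -= c
            orders[index[lbl], j] = c
        for lbl, c in t.output_multiset.items():
            stoich[index[lbl], j] += c
    return ODESystem(variables=variables, stoichiometry=stoich,
                     rates=rates, kinetic_orders=orders)


def simulate(odes: ODESystem, init: dict[str, float], t_end: float,
             P: int = 100, rtol: float = 1e-8, atol: float = 1e-10,
             neg_tol: float | None = None) -> TimeSeries:
    """Integrate the system and sample P uniform points on [0, t_end].

    Uses a stiff-capable implicit scheme (LSODA with the analytic Jacobian).
    Sampled values more negative than ``-neg_tol`` (default: 100 * atol,
    floored at 1e-9) raise; smaller undershoots are clipped to 0.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if P < 2:
        raise ValueError("need P >= 2 sample points")
    if neg_tol is None:
        neg_tol = max(1e-9, 100.0 * atol)
    missing = [v for v in odes.variables if v not in init]
    if missing:
        raise ValueError(f"initial concentrations missing for {missing}")
    x0 = np.array([float(init[v]) for v in odes.variables])
    if np.any(x0 < 0):
        raise ValueError("initial concentrations must be non-negative")
    t_eval = np.linspace(0.0, t_end, P)
    if odes.stoichiometry.shape[1] == 0:
        values = np.repeat(x0[:, None], P, axis=1)
        return TimeSeries(species=odes.variables, t0=0.0,
                          dt=t_end / (P - 1), values=values)
    y, info = odeint(
        lambda x, _t: odes.rhs(_t, x), x0, t_eval,
        Dfun=lambda x, _t: odes.jacobian(_t, x),
        rtol=rtol, atol=atol, full_output=True, mxstep=50_000,
    )
    if info["message"] != "Integration successful.":
        raise IntegrationError(f"ODE integration failed: {info['message']}")
    values = y.T
    if np.any(values < -neg_tol):
        raise IntegrationError(
            f"negative concentration below tolerance: min {values.min():.3e}"
        )
    values = np.clip(values, 0.0, None)
    return TimeSeries(species=odes.variables, t0=0.0,
                      dt=t_end / (P - 1), values=values)
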