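"""Simulated-annealing fitting of kinetic rate constants.

The model structure is fixed; the search state is the positive rate-constant
vector.  Proposals are multiplicative log-normal perturbations clipped to
bounds; moves are accepted by the Metropolis criterion and the temperature
cools geometrically from ``t_init`` to ``t_min``.  The energy of a rate
vector is the behaviour distance between the simulated and the target time
series over their shared species.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .petri import PetriNetModel
from .quantitative import IntegrationError, model_to_odes, simulate
from .fitness import behaviour_distance

__all__ = ["SAConfig", "SATraceRow", "propose_rates", "metropolis_accept",
           "run_sa", "temperature_ladder"]


@dataclass
class SAConfig:
    """Annealing settings.  Defaults keep the initial temperature moderate
    and the per-temperature iteration count at 50; higher values slow
    convergence without improving the fits on the systems studied here."""

    t_init: float = 10.0
    t_min: float = 1e-3
    alpha: float = 0.9
    iter_num: int = 50
    proposal_sigma: float = 0.2
    rate_bounds: tuple[float, float] = (1e-6, 1e3)
    rng_seed: int = 0
    sim_rtol: float = 1e-4
    sim_atol: float = 1e-7

    def __post_init__(self) -> None:
        if not (0 < self.t_min < self.t_init):
            raise ValueError("need 0 < t_min < t_init")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        lo, hi = self.rate_bounds
        if not (0 < lo < hi):
            raise ValueError("rate bounds must be ordered and positive")
        if self.proposal_sigma < 0:
            raise ValueError("proposal sigma must be >= 0")


@dataclass(frozen=True)
class SATraceRow:
    temperature: float
    iteration: int
    energy: float
    accepted: bool


def temperature_ladder(config: SAConfig) -> np.ndarray:
    """Temperatures visited by the geometric schedule t_init * alpha^j >= t_min."""
    n = int(np.floor(np.log(config.t_min / config.t_init)
                     / np.log(config.alpha))) + 1
    return config.t_init * config.alpha ** np.arange(max(n, 1))


def propose_rates(k: np.ndarray, sigma: float,
                  bounds: tuple[float, float],
                  rng: np.random.Generator) -> np.ndarray:
    """Log-normal multiplicative proposal, clipped to the rate bounds."""
    k = np.asarray(k, dtype=float)
    proposal = k * np.exp(sigma * rng.standard_normal(k.shape))
    return np.clip(proposal, bounds[0], bounds[1])


def metropolis_accept(delta_e: float, t: float,
                      rng: np.random.Generator) -> bool:
    """Accept downhill moves always, uphill with probability exp(-dE/t)."""
    if t <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    return rng.random() < np.exp(-delta_e / t)


def _set_rates(model: PetriNetModel, rates: Sequence[float]) -> PetriNetModel:
    out = model.copy()
    out.transitions = [replace(t, rate_constant=float(k))
                       for t, k in zip(out.transitions, rates)]
    return out


def run_sa(model: PetriNetModel, target, config: SAConfig,
           rng: np.random.Generator | None = None,
           subset: set[str] | None = None,
           ) -> tuple[PetriNetModel, list[SATraceRow]]:
    """Anneal the rate vector of ``model`` against a target time series.

    Returns the best-energy model seen and the full trace.  Proposals whose
    simulation fails are rejected and the loop continues.
    """
    if not model.transitions:
        raise ValueError("model has no transitions to fit")
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    shared = [s for s in target.species if model.has_species(s)]
    if not shared:
        raise ValueError("model shares no species with the target series")

    t_end = target.t0 + target.dt * (target.n_points - 1)
    init = model.initial_concentrations()

    def energy(rates: np.ndarray) -> float:
        odes = model_to_odes(_set_rates(model, rates))
        ts = simulate(odes, init, t_end=t_end, P=target.n_points,
                      rtol=config.sim_rtol, atol=config.sim_atol)
        return behaviour_distance(target, ts, subset=subset).d

    lo, hi = config.rate_bounds
    current = np.clip([t.rate_constant for t in model.transitions], lo, hi)
    current_e = energy(current)
    best, best_e = current.copy(), current_e
    trace: list[SATraceRow] = []

    for t in temperature_ladder(config):
        for i in range(config.iter_num):
            proposal = propose_rates(current, config.proposal_sigma,
                                     config.rate_bounds, rng)
            try:
                e = energy(proposal)
            except IntegrationError:
                trace.append(SATraceRow(float(t), i, float("nan"), False))
                continue
            accept = metropolis_accept(e - current_e, float(t), rng)
            if accept:
                current, current_e = proposal, e
                if e < best_e:
                    best, best_e = proposal.copy(), e
            trace.append(SATraceRow(float(t), i, e, accept))
    return _set_rates(model, best), trace
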