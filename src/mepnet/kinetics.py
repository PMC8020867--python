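"""In-vivo rate constants from the regulated steady state, and full mass-action ODEs.

At the regulated maximum-entropy-production steady state the net flux of every
reaction is known along with its concentrations and activity, so forward rate
constants follow from the mass-action flux decomposition

    zeta_net = lambda * k_fwd * prod_react n^{|gamma|} * (1 - Q/K),

i.e. k_fwd = zeta_net / (lambda * prod_react n^{|gamma|} * (1 - Q/K)), and
detailed balance (the Haldane relation) fixes k_rev = k_fwd / K.  When the net
flux carries the Marcelin form c*lambda*(K/Q - Q/K) this reduces to the
singularity-free closed form k_fwd = c * (1 + K/Q) / prod_react n^{|gamma|},
which is also the correct continuous limit for equilibrated (zero-net-flux)
branches, preserving the Marcelin relaxation timescale there.

With those constants, the ordinary mass-action ODEs

    dn_i/dt = sum_alpha gamma_{i,alpha} lambda_alpha
              (k_fwd prod_react n^{|gamma|} - k_rev prod_prod n^{gamma})

reproduce the regulated steady state as a fixed point by construction; the
simulation module integrates them with a stiff solver.  Michaelis-Menten enzyme
forms are deliberately absent: reactions are summary reactions, not
enzyme-intermediate mechanisms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .netmodel import NetworkModel
from .maxent import SteadyStateResult, _activities
from .thermo import SystemState, affinities_over_rt

__all__ = [
    "RateConstants",
    "SimulationTrajectory",
    "infer_rate_constants",
    "mass_action_rhs",
    "simulate",
    "estimate_relaxation_time",
]

_HALDANE_RTOL = 1.0e-9
# below this |1 - Q/K| the generic quotient is numerically 0/0; use the limit form
_EQUILIBRIUM_TOL = 1.0e-9


@dataclass
class RateConstants:
    """Forward/reverse rate constants for one reaction, obeying the Haldane
    relation k_fwd / k_rev = K."""

    reaction_id: str
    k_fwd: float
    k_rev: float

    def __post_init__(self) -> None:
        if self.k_fwd <= 0 or self.k_rev <= 0:
            raise ValueError(f"{self.reaction_id}: rate constants must be > 0")


@dataclass
class SimulationTrajectory:
    """Sampled mass-action trajectory: times, M x T concentrations, Z x T net fluxes."""

    times: np.ndarray
    states: np.ndarray
    fluxes: np.ndarray
    model: NetworkModel

    def state_at(self, k: int) -> SystemState:
        return SystemState(self.model, self.states[:, k], t=float(self.times[k]))

    @property
    def final_state(self) -> SystemState:
        return self.state_at(-1)


def infer_rate_constants(
    result: SteadyStateResult,
    model: NetworkModel,
    rules: Sequence | None = None,
    c: float | None = None,
) -> list[RateConstants]:
    """Infer k_fwd, k_rev for every reaction from a converged steady state.

    Uses the flux decomposition above with the result's own net fluxes and
    activities; reactions at (numerical) equilibrium fall back to the exact
    limit k_fwd = 2c / prod_react n^{|gamma|} via the closed form
    c*(1+K/Q)/prod_react n.  Raises on inconsistent input (zero driving force
    with non-negligible flux).
    """
    if not result.converged:
        raise ValueError("rate inference requires a converged steady state")
    c = result.c if c is None else c
    conc = result.state.conc
    lam = _activities(model, conc, rules)
    a = affinities_over_rt(model, conc)  # ln(K/Q)
    out: list[RateConstants] = []
    for j, r in enumerate(model.reactions):
        prod_react = 1.0
        for met, coef in r.stoich.items():
            if coef < 0:
                prod_react *= conc[model.metabolite_index(met)] ** (-coef)
        q_over_k = math.exp(-a[j]) if a[j] > -700 else math.inf
        drive = 1.0 - q_over_k
        flux = result.net_flux[j]
        if abs(drive) > _EQUILIBRIUM_TOL:
            k_fwd = flux / (lam[j] * prod_react * drive)
        else:
            if abs(flux) > _EQUILIBRIUM_TOL * max(1.0, abs(c)):
                raise ValueError(
                    f"reaction {r.id!r}: zero driving force but non-zero flux"
                )
            # equilibrated branch: limit of the quotient, Marcelin timescale kept
            k_fwd = c * (1.0 + math.exp(a[j])) / prod_react
        if k_fwd <= 0 or not math.isfinite(k_fwd):
            raise ValueError(f"reaction {r.id!r}: inferred k_fwd = {k_fwd!r}")
        out.append(RateConstants(reaction_id=r.id, k_fwd=k_fwd, k_rev=k_fwd / r.keq))
    return out


def _rate_arrays(model: NetworkModel, rates: Sequence[RateConstants]):
    by_id = {rc.reaction_id: rc for rc in rates}
    missing = [r.id for r in model.reactions if r.id not in by_id]
    if missing:
        raise ValueError(f"rate constants missing for reactions: {missing}")
    kf = np.array([by_id[r.id].k_fwd for r in model.reactions])
    kr = np.array([by_id[r.id].k_rev for r in model.reactions])
    return kf, kr


def _net_rates(
    model: NetworkModel,
    conc: np.ndarray,
    kf: np.ndarray,
    kr: np.ndarray,
    lam: np.ndarray,
) -> np.ndarray:
    """lambda * (k_fwd prod_react n^{|gamma|} - k_rev prod_prod n^{gamma}) per reaction,
    evaluated in log space."""
    ln_n = np.log(conc)
    S = model.S
    react_pow = np.where(S < 0, -S, 0.0)  # |gamma| over reactants
    prod_pow = np.where(S > 0, S, 0.0)
    fwd = np.exp(np.log(kf) + react_pow.T @ ln_n)
    rev = np.exp(np.log(kr) + prod_pow.T @ ln_n)
    return lam * (fwd - rev)


def mass_action_rhs(
    model: NetworkModel,
    state: SystemState,
    rates: Sequence[RateConstants],
    rules: Sequence | None = None,
) -> np.ndarray:
    """dn_i/dt under ordinary mass-action kinetics with regulation; boundary
    derivatives zeroed."""
    kf, kr = _rate_arrays(model, rates)
    lam = _activities(model, state.conc, rules)
    net = _net_rates(model, state.conc, kf, kr, lam)
    if not np.all(np.isfinite(net)):
        bad = [model.reactions[j].id for j in np.where(~np.isfinite(net))[0]]
        raise FloatingPointError(f"non-finite mass-action rate for reactions: {bad}")
    dndt = model.S @ net
    dndt[model.boundary_mask] = 0.0
    return dndt


def simulate(
    model: NetworkModel,
    init: SystemState,
    rates: Sequence[RateConstants],
    rules: Sequence | None = None,
    horizon: float = 10.0,
    n_samples: int = 101,
    rtol: float = 1.0e-9,
    atol: float = 1.0e-12,
    method: str = "BDF",
) -> SimulationTrajectory:
    """Stiff integration of the mass-action ODEs over [0, horizon].

    Integrates log-concentrations of the variable species; boundary species
    stay clamped.  Raises with the last accepted state on integrator failure.
    """
    kf, kr = _rate_arrays(model, rates)
    boundary = model.boundary_mask
    var = ~boundary
    conc0 = init.conc.copy()

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        conc = conc0.copy()
        conc[var] = np.exp(y)
        lam = _activities(model, conc, rules)
        net = _net_rates(model, conc, kf, kr, lam)
        return (model.S[var] @ net) / conc[var]

    times = np.linspace(0.0, horizon, n_samples)
    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        np.log(conc0[var]),
        t_eval=times,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"mass-action integration failed at t={sol.t[-1] if len(sol.t) else 0:g}: "
            f"{sol.message}"
        )
    states = np.tile(conc0[:, None], (1, len(sol.t)))
    states[var, :] = np.exp(sol.y)
    fluxes = np.empty((model.n_reactions, len(sol.t)))
    for k in range(len(sol.t)):
        lam = _activities(model, states[:, k], rules)
        fluxes[:, k] = _net_rates(model, states[:, k], kf, kr, lam)
    return SimulationTrajectory(times=sol.t, states=states, fluxes=fluxes, model=model)


def estimate_relaxation_time(
    model: NetworkModel,
    state: SystemState,
    rates: Sequence[RateConstants],
    rules: Sequence | None = None,
    eps: float = 1.0e-7,
) -> float:
    """Slowest relaxation time 1/|Re lambda_min| of the mass-action Jacobian at
    ``state`` (finite differences over the variable species; conserved/zero
    modes are ignored)."""
    var = np.where(~model.boundary_mask)[0]
    n = len(var)
    f0 = mass_action_rhs(model, state, rates, rules)[var]
    J = np.zeros((n, n))
    for k, i in enumerate(var):
        pert = state.conc.copy()
        h = eps * max(pert[i], 1e-30)
        pert[i] += h
        J[:, k] = (mass_action_rhs(model, SystemState(model, pert), rates, rules)[var] - f0) / h
    eig = np.linalg.eigvals(J)
    rates_re = np.abs(eig.real)
    rates_re = rates_re[rates_re > 1e-12 * max(1.0, rates_re.max(initial=0.0))]
    if len(rates_re) == 0:
        return math.inf
    return float(1.0 / rates_re.min())
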