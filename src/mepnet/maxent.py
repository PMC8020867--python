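"""Maximum-entropy-production steady state via the Marcelin equation.

The Marcelin form of mass-action dynamics replaces every unidirectional rate by
a single shared relaxation constant c, so the dynamics are governed purely by
thermodynamics:

    dn_i/dt = c * sum_alpha gamma_{i,alpha} * lambda_alpha *
              (e^{A_alpha/RT} - e^{-A_alpha/RT}),

with boundary (clamped) species held fixed.  Integrating this ODE to a steady
state yields the thermodynamically optimal (lowest free-energy, maximum
entropy production) non-equilibrium steady state compatible with the boundary
conditions: the unregulated free-energy surface is convex, so no multi-start
search is needed.  At that state the net flux through each reaction is

    zeta_net_alpha = c * lambda_alpha * (e^{A/RT} - e^{-A/RT}),

proportional to the net thermodynamic odds; lambda_alpha = 1 without
regulation.  The state is simultaneously a kinetic steady state (S . zeta = 0)
and a thermodynamic one (S . (K+Q- - K-Q+) . 1 = 0); both residuals are
reported separately.

Integration runs in log-concentration space by default, because unregulated
runs can span more than 25 orders of magnitude in concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .netmodel import NetworkModel
from .thermo import ReactionThermo, SystemState, affinities_over_rt

__all__ = [
    "OptimizerOptions",
    "SteadyStateResult",
    "marcelin_rhs",
    "optimize_to_steady_state",
    "evaluate_state",
    "verify_thermodynamic_stability",
]

# exp argument clip: keeps e^{A/RT} finite on wild transients without
# affecting any converged answer (|A|/RT at convergence is O(10))
_A_CLIP = 500.0


@dataclass
class OptimizerOptions:
    """Knobs for the Marcelin steady-state search.

    c is the shared relaxation constant; it sets the time unit only — the
    steady state itself is invariant to it.  ``steady_tol`` bounds the scaled
    flux-imbalance residual ||S . zeta||_inf / (gross turnover) below which the
    state counts as steady: a rounding-robust relative criterion equivalent in
    spirit to max_i |dn_i/dt|/n_i but achievable in double precision for
    ultratrace species.
    """

    c: float = 1.0
    atol: float = 1.0e-10
    rtol: float = 1.0e-8
    steady_tol: float = 1.0e-9
    t_max: float = 1.0e12
    log_space: bool = True
    method: str = "BDF"
    store_trajectory: bool = False
    #: scaled residual below which a Newton polish of the algebraic
    #: steady-state system is attempted (pseudo-transient continuation)
    newton_trigger: float = 1.0e-2
    #: per-reaction relaxation override (length Z); None keeps c_alpha = c,
    #: the central modeling assumption
    c_per_reaction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.atol <= 0 or self.rtol <= 0 or self.steady_tol <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class SteadyStateResult:
    """Converged (or best-effort) steady state with per-reaction thermodynamics."""

    state: SystemState
    net_flux: np.ndarray
    thermo: list[ReactionThermo]
    converged: bool
    residual: float
    thermo_residual: float
    c: float = 1.0
    activities: np.ndarray | None = None
    trajectory: list[SystemState] | None = None
    message: str = ""

    def flux(self, rxn_id: str) -> float:
        return float(self.net_flux[self.state.model.reaction_index(rxn_id)])


def _activities(model: NetworkModel, conc: np.ndarray, regulation) -> np.ndarray:
    """Per-reaction activity vector lambda in (0, 1]; identity without rules."""
    lam = np.ones(model.n_reactions)
    if regulation:
        from .regulation import hill_activity  # deferred: avoids import cycle

        for rule in regulation:
            j = model.reaction_index(rule.reaction_id)
            lam[j] = hill_activity(rule, conc[model.metabolite_index(rule.modulator_id)])
    return lam


def _net_odds(model: NetworkModel, conc: np.ndarray) -> np.ndarray:
    """e^{A/RT} - e^{-A/RT} per reaction, evaluated in log space."""
    a = np.clip(affinities_over_rt(model, conc), -_A_CLIP, _A_CLIP)
    return np.exp(a) - np.exp(-a)


def marcelin_rhs(
    model: NetworkModel,
    state: SystemState,
    options: OptimizerOptions | None = None,
    regulation: Sequence | None = None,
) -> np.ndarray:
    """dn_i/dt under the Marcelin equation; boundary derivatives are zero."""
    options = options or OptimizerOptions()
    conc = state.conc
    net = _net_odds(model, conc)
    if not np.all(np.isfinite(net)):
        bad = [model.reactions[j].id for j in np.where(~np.isfinite(net))[0]]
        raise FloatingPointError(f"non-finite thermodynamic odds for reactions: {bad}")
    lam = _activities(model, conc, regulation)
    c_vec = options.c_per_reaction if options.c_per_reaction is not None else options.c
    dndt = model.S @ (c_vec * lam * net)
    dndt[model.boundary_mask] = 0.0
    return dndt


def _imbalance(model: NetworkModel, rates: np.ndarray, floor: float = 0.0) -> float:
    """Scaled steady-state residual over variable metabolites.

    ||S_var . rates||_inf normalized by max(largest gross turnover, floor);
    the floor (typically the relaxation constant c, the natural Marcelin rate
    scale) lets near-equilibrium systems converge: without it the ratio of a
    single vanishing net rate to its own magnitude would never drop.
    Dimensionless; zero at equilibrium and at an exact driven steady state.
    """
    var = ~model.boundary_mask
    if not var.any():
        return 0.0
    net = model.S[var] @ rates
    gross = np.abs(model.S[var]) @ np.abs(rates)
    scale = max(float(np.max(gross)), floor)
    if scale == 0.0:
        return 0.0
    return float(np.max(np.abs(net))) / scale


def optimize_to_steady_state(
    model: NetworkModel,
    init: SystemState | None = None,
    options: OptimizerOptions | None = None,
    regulation: Sequence | None = None,
) -> SteadyStateResult:
    """Integrate the Marcelin ODE with clamped boundary species until steady.

    Pseudo-transient continuation: a stiff implicit integrator advances the
    Marcelin ODE over geometrically growing time windows; once the scaled
    flux-imbalance residual falls below ``newton_trigger`` a Newton solve of
    the algebraic steady-state system S_var . zeta(ln n) = 0 polishes the
    state to ``steady_tol``.  Conservation laws among the variable species
    (closed pools) are detected and preserved: the Newton system swaps the
    dependent balance rows for conserved-total constraints anchored at the
    initial state.  Non-convergence within ``t_max`` is reported, never
    silent.
    """
    options = options or OptimizerOptions()
    if init is None:
        init = SystemState(model, model.initial_concentrations())
    if init.model is not model:
        raise ValueError("init state was built for a different model")
    boundary = model.boundary_mask
    var = ~boundary
    conc0 = init.conc.copy()
    c = options.c
    trajectory: list[SystemState] | None = [] if options.store_trajectory else None

    if not var.any():  # fully clamped model: trivially steady
        return _finish(model, conc0, options, regulation, True, 0.0, trajectory)

    c_vec = options.c_per_reaction if options.c_per_reaction is not None else c

    c_floor = float(np.max(np.atleast_1d(c_vec)))

    def rates_at(conc: np.ndarray) -> np.ndarray:
        return c_vec * _activities(model, conc, regulation) * _net_odds(model, conc)

    def rhs_log(t: float, y: np.ndarray) -> np.ndarray:
        conc = conc0.copy()
        conc[var] = np.exp(y)
        return (model.S[var] @ rates_at(conc)) / conc[var]

    def rhs_lin(t: float, y: np.ndarray) -> np.ndarray:
        conc = conc0.copy()
        conc[var] = y
        return model.S[var] @ rates_at(conc)

    def conc_of(y: np.ndarray) -> np.ndarray:
        conc = conc0.copy()
        conc[var] = np.exp(y) if options.log_space else y
        return conc

    if options.log_space:
        y = np.log(conc0[var])
        rhs = rhs_log
    else:
        y = conc0[var].copy()
        rhs = rhs_lin

    # Conservation laws among variable species (closed pools, e.g. a TCA
    # backbone with no anaplerosis) make S_var rank-deficient; the Newton
    # polish then replaces the dependent balance rows with conserved-total
    # constraints anchored at the initial state, so the polish lands on the
    # same invariant manifold the ODE trajectory lives on.
    from scipy.linalg import null_space, qr

    S_var = model.S[var]
    n_var = int(var.sum())
    rank = np.linalg.matrix_rank(S_var)
    if rank < n_var:
        _, _, piv = qr(S_var.T, pivoting=True)
        indep_rows = np.sort(piv[:rank])
        L = null_space(S_var.T).T  # conservation basis: L @ S_var = 0
        L_scale = np.abs(L) @ conc0[var]
        totals0 = L @ conc0[var]
    else:
        indep_rows = np.arange(n_var)
        L = None

    def try_newton(y_log: np.ndarray, current: float):
        """Newton polish; works in log space regardless of the ODE variable."""
        from scipy.optimize import root

        def g(yv: np.ndarray) -> np.ndarray:
            conc = conc0.copy()
            conc[var] = np.exp(yv)
            net = S_var @ rates_at(conc)
            if L is None:
                return net
            cons = (L @ conc[var] - totals0) / L_scale * c_floor
            return np.concatenate([net[indep_rows], cons])

        sol = root(g, y_log, method="hybr")
        if sol.success and np.all(np.isfinite(sol.x)):
            conc = conc0.copy()
            conc[var] = np.exp(sol.x)
            resid = _imbalance(model, rates_at(conc), c_floor)
            if resid < current:
                return sol.x, resid
        return None

    # window sequence in units of 1/c
    t_lo = 0.0
    t_hi = 1.0e-3 / c
    converged = False
    message = ""
    residual = _imbalance(model, rates_at(conc_of(y)), c_floor)
    while t_hi <= options.t_max / c:
        sol = solve_ivp(
            rhs,
            (t_lo, t_hi),
            y,
            method=options.method,
            rtol=options.rtol,
            atol=options.atol,
        )
        if len(sol.y) and sol.y.shape[1]:
            y = sol.y[:, -1]
        if trajectory is not None:
            trajectory.append(SystemState(model, conc_of(y), t=sol.t[-1]))
        if not np.all(np.isfinite(conc_of(y))) or np.any(conc_of(y) <= 0):
            message = "concentration underflow during integration"
            break
        residual = _imbalance(model, rates_at(conc_of(y)), c_floor)
        if residual < options.newton_trigger:
            polished = try_newton(
                y.copy() if options.log_space else np.log(conc_of(y)[var]), residual
            )
            if polished is not None:
                y_pol, residual = polished
                y = y_pol if options.log_space else np.exp(y_pol)
        if residual < options.steady_tol:
            converged = True
            break
        if not sol.success:
            message = f"integrator failed in window ending t={t_hi:g}: {sol.message}"
            break
        t_lo, t_hi = t_hi, t_hi * 10.0
    else:
        message = f"no steady state within t_max={options.t_max:g}/c"
    return _finish(
        model, conc_of(y), options, regulation, converged, residual, trajectory, message
    )


def _finish(
    model: NetworkModel,
    conc: np.ndarray,
    options: OptimizerOptions,
    regulation,
    converged: bool,
    residual: float,
    trajectory,
    message: str = "",
) -> SteadyStateResult:
    state = SystemState(model, conc)
    net = _net_odds(model, conc)
    lam = _activities(model, conc, regulation)
    c_vec = options.c_per_reaction if options.c_per_reaction is not None else options.c
    net_flux = c_vec * lam * net
    a = affinities_over_rt(model, conc)
    rt = model.RT
    def _safe_exp(x: float) -> float:
        return math.exp(x) if x < 700 else math.inf

    thermo = [
        ReactionThermo(
            reaction_id=r.id,
            Q=_safe_exp(math.log(r.keq) - a[j]),
            A_over_RT=a[j],
            odds=_safe_exp(min(max(a[j], -_A_CLIP), _A_CLIP)),
            dG=-rt * a[j],
        )
        for j, r in enumerate(model.reactions)
    ]
    var = ~model.boundary_mask
    flux_scale = max(1.0, float(np.max(np.abs(net_flux))) if len(net_flux) else 1.0)
    thermo_res = (
        float(np.max(np.abs(model.S[var] @ (lam * net)))) / max(1.0, float(np.max(np.abs(lam * net))))
        if var.any()
        else 0.0
    )
    return SteadyStateResult(
        state=state,
        net_flux=net_flux,
        thermo=thermo,
        converged=converged,
        residual=residual,
        thermo_residual=thermo_res,
        c=options.c,
        activities=lam,
        trajectory=trajectory,
        message=message,
    )


def evaluate_state(
    model: NetworkModel,
    state: SystemState,
    options: OptimizerOptions | None = None,
    regulation: Sequence | None = None,
) -> SteadyStateResult:
    """Assemble a SteadyStateResult (fluxes, thermodynamics, residuals) for an
    arbitrary state without integrating; ``converged`` reflects whether the
    state already satisfies the steady criterion."""
    options = options or OptimizerOptions()
    conc = state.conc.copy()
    c_vec = options.c_per_reaction if options.c_per_reaction is not None else options.c
    rates = c_vec * _activities(model, conc, regulation) * _net_odds(model, conc)
    residual = _imbalance(model, rates, float(np.max(np.atleast_1d(c_vec))))
    return _finish(
        model,
        conc,
        options,
        regulation,
        residual < options.steady_tol,
        residual,
        None,
    )


def verify_thermodynamic_stability(
    result: SteadyStateResult, model: NetworkModel, regulation: Sequence | None = None
) -> float:
    """Scaled thermodynamic-stability residual ||S . (lambda (K+Q- - K-Q+)) . 1||_inf
    over variable metabolites, normalized by the largest net odds.

    Zero at full equilibrium; below ``steady_tol`` scale at a converged
    maximum-entropy-production steady state.  ``regulation`` folds activities
    in; omit it for the bare (unregulated) form.
    """
    conc = result.state.conc
    net = _net_odds(model, conc)
    lam = _activities(model, conc, regulation)
    var = ~model.boundary_mask
    if not var.any():
        return float(np.max(np.abs(model.S @ (lam * net))))
    scale = max(1.0, float(np.max(np.abs(lam * net))))
    return float(np.max(np.abs(model.S[var] @ (lam * net)))) / scale


def free_energy(model: NetworkModel, conc: np.ndarray) -> float:
    """Dimensionless free energy G/RT = sum_i n_i (mu0_i/RT + ln n_i - 1).

    A Lyapunov function of the Marcelin dynamics on closed systems (convex in
    the concentrations); requires mu0 on every metabolite.
    """
    if any(m.mu0 is None for m in model.metabolites):
        raise ValueError("free_energy requires mu0 on every metabolite")
    mu = np.array([m.mu0 for m in model.metabolites], dtype=float)
    return float(np.sum(conc * (mu / model.RT + np.log(conc) - 1.0)))
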