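"""Circuit-style characterization of reactions and stoichiometric yield analysis.

At a steady state each reaction behaves like a dissipative circuit element:

    power        P_alpha = A_alpha * zeta_net_alpha        (>= 0 at a
                 maximum-entropy-production steady state: flux runs down the
                 affinity gradient)
    resistance   R_alpha = A_alpha / zeta_net_alpha
    conductance  C_alpha = 1 / R_alpha

with A_alpha the reaction affinity in kJ/mol (equal in magnitude to the
free-energy change across the reaction at steady state; that magnitude
convention keeps R non-negative where flux is forward).  The total entropy
production rate is sum_alpha A_alpha zeta_alpha / T.  None of this implies a
linear flux/free-energy relationship: a regulated reaction carries the same
steady flux as its neighbours but at a much larger driving force, i.e. a much
larger resistance — regulation acts as a potentiometer.

Pathway yields (e.g. NADPH per glucose 6-phosphate under full pentose
recycling) are pure stoichiometry: they are solved here as an exact rational
constrained flux-balance problem (unit input, designated exits, all other
internal species balanced), independent of c, rate constants or regulation
strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
import sympy

from .netmodel import NetworkModel
from .maxent import SteadyStateResult

__all__ = [
    "CircuitRow",
    "CircuitReport",
    "YieldResult",
    "circuit_report",
    "entropy_production_rate",
    "pathway_yield",
]


@dataclass
class CircuitRow:
    reaction_id: str
    dG: float  # kJ/mol (= -A)
    flux: float
    power: float  # A * flux, kJ/mol * flux units
    resistance: float  # |A| convention: +inf sentinel where flux ~ 0
    conductance: float


@dataclass
class CircuitReport:
    rows: list[CircuitRow]
    total_entropy_production_rate: float  # sum A*flux / T, kJ/(mol K) * flux units

    def row(self, rxn_id: str) -> CircuitRow:
        for r in self.rows:
            if r.reaction_id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def to_frame(self) -> pd.DataFrame:
        """G/P/R/F-style table (minus-dG, power, resistance, flux)."""
        return pd.DataFrame(
            {
                "reaction_id": [r.reaction_id for r in self.rows],
                "minus_dG_kJ_mol": [-r.dG for r in self.rows],
                "power": [r.power for r in self.rows],
                "resistance": [r.resistance for r in self.rows],
                "flux": [r.flux for r in self.rows],
                "conductance": [r.conductance for r in self.rows],
            }
        )


def circuit_report(
    result: SteadyStateResult, model: NetworkModel, flux_tol: float = 1.0e-9
) -> CircuitReport:
    """Per-reaction circuit descriptors from a converged steady state.

    Reactions with |flux| below ``flux_tol`` relative to the flux scale
    (numerically zero at the default steady tolerance) get a +inf resistance
    sentinel and zero conductance.
    """
    rt = model.RT
    # flux scale: the relaxation constant c is the natural Marcelin rate unit,
    # so a whole-system-at-equilibrium report still gets its inf sentinels
    scale = max(float(np.max(np.abs(result.net_flux))), result.c, 1e-300)
    rows = []
    for j, r in enumerate(model.reactions):
        a_kj = rt * result.thermo[j].A_over_RT  # affinity, kJ/mol
        flux = float(result.net_flux[j])
        power = a_kj * flux
        if abs(flux) < flux_tol * scale:
            resistance, conductance = math.inf, 0.0
        else:
            resistance = a_kj / flux
            conductance = 1.0 / resistance if resistance != 0 else math.inf
        rows.append(
            CircuitRow(
                reaction_id=r.id,
                dG=-a_kj,
                flux=flux,
                power=power,
                resistance=resistance,
                conductance=conductance,
            )
        )
    total = sum(row.power for row in rows) / model.temperature
    return CircuitReport(rows=rows, total_entropy_production_rate=total)


def entropy_production_rate(result: SteadyStateResult, model: NetworkModel) -> float:
    """Total entropy production rate sum_alpha A_alpha zeta_alpha / T.

    Non-negative at any maximum-entropy-production steady state; zero only at
    full equilibrium.
    """
    rt = model.RT
    a_kj = rt * np.array([t.A_over_RT for t in result.thermo])
    return float(np.dot(a_kj, result.net_flux)) / model.temperature


@dataclass
class YieldResult:
    """Net stoichiometry of a pathway operating mode per unit input."""

    net_stoichiometry: dict[str, Fraction]
    cycle_count: Fraction | None
    fluxes: dict[str, Fraction]

    def yield_of(self, met_id: str) -> Fraction:
        return self.net_stoichiometry.get(met_id, Fraction(0))


def pathway_yield(
    model: NetworkModel,
    input_metabolite: str,
    exits: Sequence[str],
    active_reactions: Sequence[str] | None = None,
    free_metabolites: Sequence[str] | None = None,
    cycle_reaction: str | None = None,
) -> YieldResult:
    """Exact constrained flux balance: unit consumption of ``input_metabolite``,
    net production allowed only at ``exits`` and at boundary/free species, all
    other metabolites balanced.

    ``active_reactions`` restricts the flux support (reactions carrying flux in
    the operating mode under study); ``free_metabolites`` defaults to the
    model's boundary species.  The flux solution must be unique on that
    support — otherwise the rank deficiency is reported.  All arithmetic is
    rational, so integer stoichiometric yields come out integer-exact.
    ``cycle_count`` is the flux through ``cycle_reaction`` per unit input.
    """
    rxns = (
        [model.get_reaction(rid) for rid in active_reactions]
        if active_reactions is not None
        else list(model.reactions)
    )
    free = set(free_metabolites) if free_metabolites is not None else {
        m.id for m in model.metabolites if m.is_boundary
    }
    exits_set = set(exits)
    balanced = [
        m.id
        for m in model.metabolites
        if m.id not in free and m.id not in exits_set and m.id != input_metabolite
    ]
    # keep only balanced metabolites actually touched by the active reactions
    touched = set()
    for r in rxns:
        touched |= set(r.stoich)
    balanced = [m for m in balanced if m in touched]

    v = sympy.symbols(f"v0:{len(rxns)}", rational=True)
    eqs = []
    for m in balanced:
        eqs.append(sympy.Eq(sum(sympy.Rational(r.stoich.get(m, 0)) * v[j] for j, r in enumerate(rxns)), 0))
    # unit net consumption of the input
    eqs.append(
        sympy.Eq(
            sum(sympy.Rational(r.stoich.get(input_metabolite, 0)) * v[j] for j, r in enumerate(rxns)),
            -1,
        )
    )
    sol = sympy.linsolve(eqs, v)
    if sol is sympy.S.EmptySet:
        raise ValueError(
            "no steady flux vector exists with the requested boundary pattern"
        )
    (vec,) = sol
    free_syms = vec.free_symbols
    if free_syms:
        A_rank = sympy.Matrix([[sympy.Rational(r.stoich.get(m, 0)) for r in rxns] for m in balanced + [input_metabolite]]).rank()
        raise ValueError(
            f"flux solution not unique on the active support "
            f"({len(free_syms)} free modes; constraint rank {A_rank}, {len(rxns)} reactions)"
        )
    flux = {}
    for r, x in zip(rxns, vec):
        xr = sympy.Rational(x)
        flux[r.id] = Fraction(int(xr.p), int(xr.q))
    net: dict[str, Fraction] = {}
    for m in model.metabolites:
        total = sum(
            (Fraction(r.stoich[m.id]).limit_denominator() * flux[r.id] for r in rxns if m.id in r.stoich),
            Fraction(0),
        )
        if total != 0:
            net[m.id] = total
    cycle = flux.get(cycle_reaction) if cycle_reaction else None
    return YieldResult(net_stoichiometry=net, cycle_count=cycle, fluxes=flux)
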