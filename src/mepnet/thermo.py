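"""Reaction quotients, affinities, thermodynamic odds and free-energy changes.

For a reaction alpha with equilibrium constant K and reaction quotient
Q = prod_i n_i^gamma_i, the affinity (thermodynamic driving force) is

    A/RT = ln K - ln Q,

the thermodynamic odds e^{A/RT} = K/Q give the ratio of forward to reverse
unidirectional flux of a mass-action reaction (an exact fluctuation-theorem-like
identity), and dG = -A is the free-energy change.  All arithmetic is done in
log space so that states spanning tens of orders of magnitude in concentration
remain representable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netmodel import NetworkModel, Reaction

__all__ = [
    "SystemState",
    "ReactionThermo",
    "reaction_quotient",
    "affinity",
    "reaction_thermo_table",
    "fluctuation_ratio",
    "thermo_frame",
]


@dataclass
class SystemState:
    """Concentration vector (ordered as ``model.metabolites``) with a time stamp.

    Boundary metabolites must sit at their clamped values; variable metabolites
    must be strictly positive.
    """

    model: NetworkModel
    conc: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        if self.conc.shape != (self.model.n_metabolites,):
            raise ValueError(
                f"conc has shape {self.conc.shape}, model has "
                f"{self.model.n_metabolites} metabolites"
            )
        if np.any(self.conc <= 0):
            bad = [
                m.id for m, c in zip(self.model.metabolites, self.conc) if c <= 0
            ]
            raise ValueError(f"non-positive concentrations for: {bad}")

    def __getitem__(self, met_id: str) -> float:
        return float(self.conc[self.model.metabolite_index(met_id)])

    @property
    def ln_conc(self) -> np.ndarray:
        return np.log(self.conc)

    def copy(self, t: float | None = None) -> "SystemState":
        return SystemState(self.model, self.conc.copy(), self.t if t is None else t)


@dataclass
class ReactionThermo:
    """Per-reaction thermodynamic snapshot at one state.

    ``odds`` is e^{A/RT}; ``dG`` = -A in kJ/mol.
    """

    reaction_id: str
    Q: float
    A_over_RT: float
    odds: float
    dG: float


def reaction_quotient(state: SystemState, reaction: Reaction) -> float:
    """Q = prod_i n_i^{gamma_i} over all participants (clamped species at their
    clamped values).  Computed as exp(sum gamma ln n)."""
    return math.exp(_ln_q(state, reaction))


def _ln_q(state: SystemState, reaction: Reaction) -> float:
    idx = state.model.metabolite_index
    return sum(
        coef * math.log(state.conc[idx(met)]) for met, coef in reaction.stoich.items()
    )


def affinity(state: SystemState, reaction: Reaction) -> ReactionThermo:
    """Affinity A/RT = ln K - ln Q with odds K/Q and dG = -RT (A/RT) in kJ/mol."""
    if reaction.keq is None:
        raise ValueError(f"reaction {reaction.id!r} has no equilibrium constant")
    ln_q = _ln_q(state, reaction)
    a_rt = math.log(reaction.keq) - ln_q
    rt = state.model.RT
    return ReactionThermo(
        reaction_id=reaction.id,
        Q=math.exp(ln_q),
        A_over_RT=a_rt,
        odds=math.exp(a_rt) if abs(a_rt) < 700 else math.inf * math.copysign(1, a_rt),
        dG=-rt * a_rt,
    )


def ln_reaction_quotients(model: NetworkModel, conc: np.ndarray) -> np.ndarray:
    """Vector of ln Q over all reactions (vectorized: S^T ln n)."""
    return model.S.T @ np.log(conc)


def affinities_over_rt(model: NetworkModel, conc: np.ndarray) -> np.ndarray:
    """Vector of A_alpha/RT = ln K_alpha - ln Q_alpha over all reactions."""
    return model.ln_keq - ln_reaction_quotients(model, conc)


def reaction_thermo_table(state: SystemState) -> list[ReactionThermo]:
    """Per-reaction thermodynamics for every reaction in the model."""
    return [affinity(state, r) for r in state.model.reactions]


def fluctuation_ratio(fwd_rate: float, rev_rate: float) -> float:
    """Ratio of forward to reverse unidirectional rates.

    For mass-action kinetics this equals exp(A/RT) exactly — the form of a
    fluctuation theorem, holding as an identity rather than asymptotically.
    """
    if rev_rate <= 0:
        raise ValueError("reverse rate must be > 0")
    return fwd_rate / rev_rate


def thermo_frame(thermo: list[ReactionThermo]) -> pd.DataFrame:
    """TSV-ready table: reaction_id, Q, A_RT, odds, dG_kJ_mol."""
    return pd.DataFrame(
        {
            "reaction_id": [t.reaction_id for t in thermo],
            "Q": [t.Q for t in thermo],
            "A_RT": [t.A_over_RT for t in thermo],
            "odds": [t.odds for t in thermo],
            "dG_kJ_mol": [t.dG for t in thermo],
        }
    )
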