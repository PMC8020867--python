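"""Reaction-network model: metabolites, reactions, stoichiometry, thermodynamic parameters.

A :class:`NetworkModel` is the static problem definition for all downstream
analysis: an ordered metabolite list (with boundary/clamp flags, standard
chemical potentials and physiological concentration caps), an ordered reaction
list (signed stoichiometry, equilibrium constants, pathway annotations) and the
M x Z signed stoichiometric matrix S derived from them.

Conventions
-----------
* Concentrations are dimensionless activities relative to a 1 mol/L standard
  state; "mol/L" in field names refers to that scale.
* Temperature defaults to 298.15 K with R = 8.314e-3 kJ/(mol K), the
  standard-state convention of component-contribution free-energy data.
* Standard chemical potentials mu0 (kJ/mol) are *inputs*, already adjusted for
  the medium (dielectric, ionic strength, pH); this package never recomputes
  that adjustment.  Water and protons are assumed folded into each reaction's
  equilibrium constant (pH is clamped).
* Equilibrium constants obey K_alpha = exp(-sum_i gamma_{i,alpha} mu0_i / RT).
  When both mu0 and keq are given they must agree to relative 1e-6.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "R_KJ_PER_MOL_K",
    "DEFAULT_TEMPERATURE_K",
    "DEFAULT_EXPECTED_CAP_M",
    "Metabolite",
    "Reaction",
    "MediumConditions",
    "NetworkModel",
    "ModelValidationError",
    "load_model",
    "save_model",
    "stoichiometric_matrix",
]

R_KJ_PER_MOL_K = 8.314e-3
DEFAULT_TEMPERATURE_K = 298.15
#: rule-of-thumb physiological ceiling: most metabolites stay below millimolar
DEFAULT_EXPECTED_CAP_M = 1.0e-3

_KEQ_MU_RTOL = 1.0e-6


class ModelValidationError(ValueError):
    """Raised when a network model violates a structural invariant."""


@dataclass
class Metabolite:
    """One chemical species.

    Parameters
    ----------
    id:
        Short unique identifier, BiGG-style (e.g. ``"f16bp_c"``).
    mu0:
        Standard chemical potential, kJ/mol, already medium-adjusted.
        Optional when every reaction carries an explicit ``keq``.
    is_boundary:
        Clamped species: its concentration is held fixed in every system
        state built from the model (nutrients, waste, cofactor pools).
    expected_cap:
        Physiological concentration cap used by the regulation loss
        function, mol/L.
    conc0:
        Initial (and, for boundary species, clamped) concentration, mol/L.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    mu0: float | None = None
    is_boundary: bool = False
    expected_cap: float = DEFAULT_EXPECTED_CAP_M
    conc0: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if self.expected_cap <= 0:
            raise ModelValidationError(
                f"metabolite {self.id!r}: expected_cap must be > 0"
            )
        if self.is_boundary and (self.conc0 is None or self.conc0 <= 0):
            raise ModelValidationError(
                f"boundary metabolite {self.id!r} needs a positive clamped conc0"
            )


@dataclass
class Reaction:
    """One reversible reaction with signed stoichiometry.

    ``stoich`` maps metabolite id -> signed coefficient gamma (negative for
    reactants, positive for products).  Coefficients may be rational
    (e.g. 0.5); reaction quotients use exact powers.
    """

    id: str
    stoich: dict[str, float]
    keq: float | None = None
    is_transport: bool = False
    pathway_tag: str = ""
    topological_rank: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.stoich:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if any(coef == 0 for coef in self.stoich.values()):
            raise ModelValidationError(
                f"reaction {self.id!r}: zero stoichiometric coefficient"
            )
        if self.keq is not None and self.keq <= 0:
            raise ModelValidationError(f"reaction {self.id!r}: keq must be > 0")

    @property
    def reactants(self) -> list[str]:
        return [m for m, c in self.stoich.items() if c < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, c in self.stoich.items() if c > 0]


@dataclass
class MediumConditions:
    """Cytoplasmic medium descriptors (metadata only; mu0 values arrive
    pre-adjusted for these conditions)."""

    dielectric: float = 78.5
    ionic_strength: float = 0.25
    pH: float = 7.0

    def __post_init__(self) -> None:
        if self.ionic_strength < 0:
            raise ModelValidationError("ionic_strength must be >= 0")
        if not (0 < self.pH < 14):
            raise ModelValidationError("pH must lie in (0, 14)")


@dataclass
class NetworkModel:
    """Validated reaction network with thermodynamic parameterization."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    medium: MediumConditions = field(default_factory=MediumConditions)
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        self._validate()
        self._index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._fill_keq()
        self._S = self._build_S()

    # -- derived quantities -------------------------------------------------

    @property
    def RT(self) -> float:
        """RT in kJ/mol (2.4790 at the default 298.15 K)."""
        return R_KJ_PER_MOL_K * self.temperature

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def S(self) -> np.ndarray:
        """M x Z signed stoichiometric matrix (rows = metabolites, cols = reactions)."""
        return self._S

    def metabolite_index(self, met_id: str) -> int:
        return self._index[met_id]

    def reaction_index(self, rxn_id: str) -> int:
        for i, r in enumerate(self.reactions):
            if r.id == rxn_id:
                return i
        raise KeyError(rxn_id)

    def get_reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self.reaction_index(rxn_id)]

    @property
    def boundary_mask(self) -> np.ndarray:
        """Boolean vector over metabolites; True where clamped."""
        return np.array([m.is_boundary for m in self.metabolites], dtype=bool)

    @property
    def keq_vector(self) -> np.ndarray:
        return np.array([r.keq for r in self.reactions], dtype=float)

    @property
    def ln_keq(self) -> np.ndarray:
        return np.log(self.keq_vector)

    def caps_vector(self) -> np.ndarray:
        return np.array([m.expected_cap for m in self.metabolites], dtype=float)

    def initial_concentrations(
        self, default: float = 1.0e-6, overrides: Mapping[str, float] | None = None
    ) -> np.ndarray:
        """Concentration vector from per-metabolite ``conc0`` (falling back to
        ``default`` for variable species without one), with optional overrides."""
        conc = np.empty(self.n_metabolites)
        for i, m in enumerate(self.metabolites):
            conc[i] = m.conc0 if m.conc0 is not None else default
        if overrides:
            for met_id, value in overrides.items():
                conc[self._index[met_id]] = value
        if np.any(conc <= 0):
            raise ModelValidationError("initial concentrations must be positive")
        return conc

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dupes}")
        known = set(met_ids)
        touched: set[str] = set()
        for r in self.reactions:
            unknown = set(r.stoich) - known
            if unknown:
                raise ModelValidationError(
                    f"reaction {r.id!r} references unknown metabolites: {sorted(unknown)}"
                )
            touched |= set(r.stoich)
            has_reac = any(c < 0 for c in r.stoich.values())
            has_prod = any(c > 0 for c in r.stoich.values())
            if not (has_reac and has_prod):
                raise ModelValidationError(
                    f"reaction {r.id!r} must have both reactants and products"
                )
        orphans = known - touched
        if orphans:
            raise ModelValidationError(
                f"metabolites participate in no reaction (all-zero S rows): {sorted(orphans)}"
            )
        if self.temperature <= 0:
            raise ModelValidationError("temperature must be > 0 K")

    def _fill_keq(self) -> None:
        """Compute K from mu0 where absent; cross-check where both present."""
        mu = {m.id: m.mu0 for m in self.metabolites}
        for r in self.reactions:
            have_mu = all(mu[m] is not None for m in r.stoich)
            if have_mu:
                ln_k = -sum(coef * mu[m] for m, coef in r.stoich.items()) / self.RT
                k_from_mu = math.exp(ln_k)
                if r.keq is None:
                    r.keq = k_from_mu
                elif abs(math.log(r.keq) - ln_k) > _KEQ_MU_RTOL:
                    raise ModelValidationError(
                        f"reaction {r.id!r}: keq={r.keq:g} inconsistent with mu0 "
                        f"(implies {k_from_mu:g})"
                    )
            elif r.keq is None:
                raise ModelValidationError(
                    f"reaction {r.id!r}: neither keq nor complete mu0 coverage available"
                )

    def _build_S(self) -> np.ndarray:
        S = np.zeros((self.n_metabolites, self.n_reactions))
        for a, r in enumerate(self.reactions):
            for m, coef in r.stoich.items():
                S[self._index[m], a] = coef
        return S

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "temperature_K": self.temperature,
            "medium": {
                "dielectric": self.medium.dielectric,
                "ionic_strength_M": self.medium.ionic_strength,
                "pH": self.medium.pH,
            },
            "metabolites": [
                {
                    "id": m.id,
                    "name": m.name,
                    "compartment": m.compartment,
                    "mu0_kJ_mol": m.mu0,
                    "is_boundary": m.is_boundary,
                    "expected_cap_M": m.expected_cap,
                    "conc0_M": m.conc0,
                }
                for m in self.metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoich": dict(r.stoich),
                    "keq": r.keq,
                    "is_transport": r.is_transport,
                    "pathway_tag": r.pathway_tag,
                    "topological_rank": r.topological_rank,
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "NetworkModel":
        medium_doc = doc.get("medium", {})
        medium = MediumConditions(
            dielectric=medium_doc.get("dielectric", 78.5),
            ionic_strength=medium_doc.get("ionic_strength_M", 0.25),
            pH=medium_doc.get("pH", 7.0),
        )
        metabolites = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                mu0=m.get("mu0_kJ_mol"),
                is_boundary=bool(m.get("is_boundary", False)),
                expected_cap=m.get("expected_cap_M", DEFAULT_EXPECTED_CAP_M),
                conc0=m.get("conc0_M"),
            )
            for m in doc["metabolites"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                stoich={k: float(v) for k, v in r["stoich"].items()},
                keq=r.get("keq"),
                is_transport=bool(r.get("is_transport", False)),
                pathway_tag=r.get("pathway_tag", ""),
                topological_rank=int(r.get("topological_rank", 0)),
            )
            for r in doc["reactions"]
        ]
        return cls(
            metabolites=metabolites,
            reactions=reactions,
            medium=medium,
            temperature=doc.get("temperature_K", DEFAULT_TEMPERATURE_K),
        )


def load_model(source: str | Path | Mapping) -> NetworkModel:
    """Load and validate a model from a JSON document (path, JSON string, or dict)."""
    if isinstance(source, Mapping):
        return NetworkModel.from_dict(source)
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("{")
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    return NetworkModel.from_dict(json.loads(text))


def save_model(model: NetworkModel, sink: str | Path | None = None) -> str:
    """Serialize a model to JSON; write to ``sink`` when given. Round-trips exactly."""
    text = json.dumps(model.to_dict(), indent=2)
    if sink is not None:
        Path(sink).write_text(text + "\n")
    return text


def stoichiometric_matrix(model: NetworkModel) -> np.ndarray:
    """M x Z signed stoichiometric matrix; rows follow ``model.metabolites``,
    columns follow ``model.reactions``."""
    return model.S.copy()
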