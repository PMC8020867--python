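"""Self-contained test networks: toy pairs, linear chains, and a central-carbon
metabolism emulation (glycolysis + TCA, optionally + pentose phosphate pathway).

The central-metabolism fixture mirrors the shape of a fungal central-carbon
subnetwork: 20 variable metabolites and 20 reactions (upper/lower glycolysis,
pyruvate transport and dehydrogenase, and a 9-step TCA cycle), with glucose
6-phosphate clamped at 2 mM as the driving nutrient, CO2 clamped at 0.1 mM as
the waste sink, and the cofactor pools (CoA, ATP, ADP, Pi, NAD(H), NADP(H) and
an equal-potential respiratory redox shuttle) clamped as boundary species.
Identifiers follow BiGG abbreviations.

The standard chemical potentials are a frozen emulation table — chosen once so
that the network's qualitative behaviour is that of real central metabolism
(strongly exergonic PFK/PDH steps, near-neutral isomerizations, an aldolase
split that doubles lower-pathway flux, an oxidative PPP whose drive grows with
the NADP/NADPH ratio) — not literature formation energies.  Quantitative
conclusions that depend on the exact potentials are therefore out of scope for
these fixtures; stoichiometric and ratio-based results are exact.
"""

from __future__ import annotations

from typing import Sequence

from .netmodel import Metabolite, MediumConditions, NetworkModel, Reaction
from .regulation import LossRecord
from .thermo import SystemState

__all__ = [
    "make_toy_pair",
    "make_chain",
    "make_central_metabolism",
    "make_fixture",
    "table1_records",
    "table1_pathway_metadata",
    "NADP_NADPH_PRESETS",
    "FIXTURE_NAMES",
]

#: NADP/NADPH clamp presets (ratio -> (NADP, NADPH) in mol/L): a low ratio from
#: exponential-growth mass-spectrometry estimates, a balanced pool, and a high
#: ratio matching the measured NAD/NADH pool.
NADP_NADPH_PRESETS: dict[float, tuple[float, float]] = {
    0.0175: (2.1e-6, 1.2e-4),
    1.0: (1.0e-4, 1.0e-4),
    31.0: (2.6e-3, 8.3e-5),
}

FIXTURE_NAMES = (
    "toy_pair",
    "chain",
    "glycolysis",
    "glycolysis_ppp",
    "central_metabolism",
)


def make_toy_pair(K: float = 2.0) -> NetworkModel:
    """Closed A + B <=> C + D with the given equilibrium constant (no boundary
    species; equilibrium satisfies (n_C n_D)/(n_A n_B) = K)."""
    import math

    if K <= 0:
        raise ValueError("K must be > 0")
    mu_c = -8.314e-3 * 298.15 * math.log(K)
    mets = [
        Metabolite(id="A", mu0=0.0, conc0=1.0),
        Metabolite(id="B", mu0=0.0, conc0=1.0),
        Metabolite(id="C", mu0=mu_c, conc0=1.0),
        Metabolite(id="D", mu0=0.0, conc0=1.0),
    ]
    rxns = [Reaction(id="R1", stoich={"A": -1, "B": -1, "C": 1, "D": 1})]
    return NetworkModel(metabolites=mets, reactions=rxns)


def make_chain(
    length: int,
    K_vec: Sequence[float] | None = None,
    clamp_head: float | None = None,
    clamp_tail: float | None = None,
    conc0: float = 1.0,
) -> NetworkModel:
    """Linear chain A1 <=> A2 <=> ... <=> A_L.

    ``clamp_head``/``clamp_tail`` clamp the terminal species (pass None to
    leave an end free, giving a closed relaxing system).  K defaults to 1 for
    every step.  Chemical potentials are derived from the K values
    (mu_1 = 0, mu_{j+1} = mu_j - RT ln K_j), so free-energy bookkeeping works.
    """
    import math

    if length < 2:
        raise ValueError("length must be >= 2")
    K_vec = list(K_vec) if K_vec is not None else [1.0] * (length - 1)
    if len(K_vec) != length - 1:
        raise ValueError("K_vec must have length-1 entries")
    if any(k <= 0 for k in K_vec):
        raise ValueError("all K must be > 0")
    rt = 8.314e-3 * 298.15
    mu = [0.0]
    for k in K_vec:
        mu.append(mu[-1] - rt * math.log(k))
    mets = []
    for j in range(length):
        head = j == 0 and clamp_head is not None
        tail = j == length - 1 and clamp_tail is not None
        mets.append(
            Metabolite(
                id=f"A{j + 1}",
                mu0=mu[j],
                is_boundary=head or tail,
                conc0=clamp_head if head else (clamp_tail if tail else conc0),
            )
        )
    rxns = [
        Reaction(
            id=f"R{j + 1}",
            stoich={f"A{j + 1}": -1, f"A{j + 2}": 1},
            pathway_tag="chain",
            topological_rank=j + 1,
        )
        for j in range(length - 1)
    ]
    return NetworkModel(metabolites=mets, reactions=rxns)


# ---------------------------------------------------------------------------
# central-carbon metabolism emulation
# ---------------------------------------------------------------------------

#: frozen standard chemical potentials (kJ/mol), medium-adjusted emulation table
_MU0 = {
    # clamped boundary species
    "g6p_c": 0.0,
    "co2_c": -33.0,
    "coa_m": 0.0,
    "atp_c": 0.0,
    "adp_c": 0.0,
    "pi_c": 0.0,
    "nad_c": 0.0,
    "nadh_c": 0.0,
    "q_m": 0.0,   # respiratory shuttle pair: equal potentials
    "qh2_m": 0.0,
    "nadp_c": 0.0,
    "nadph_c": 0.0,
    # glycolysis
    "f6p_c": 2.5,
    "fdp_c": -21.5,
    "dhap_c": -3.0,
    "g3p_c": 4.5,
    "13dpg_c": 9.5,
    "3pg_c": -9.5,
    "2pg_c": -5.1,
    "pep_c": -8.3,
    "pyr_c": -35.3,
    # mitochondria
    "pyr_m": -35.3,
    "accoa_m": -37.3,
    "cit_m": -27.3,
    "acon_m": -21.3,
    "icit_m": -22.3,
    "akg_m": 8.7,
    "succoa_m": 31.7,
    "succ_m": 31.7,
    "fum_m": 29.7,
    "mal_m": 26.2,
    "oaa_m": 20.0,
    # pentose phosphate pathway
    "6pgl_c": -3.0,
    "6pgc_c": -18.0,
    "ru5p_c": 7.0,
    "r5p_c": 6.5,
    "xu5p_c": 6.5,
    "s7p_c": 4.7,
    "e4p_c": 6.1,
}

#: boundary clamps (mol/L); NADP/NADPH handled by preset
_CLAMPS = {
    "g6p_c": 2.0e-3,
    "co2_c": 1.0e-4,
    "coa_m": 1.0e-3,
    "atp_c": 9.6e-3,
    "adp_c": 5.6e-4,
    "pi_c": 5.0e-3,
    "nad_c": 2.6e-3,
    "nadh_c": 8.3e-5,
    "q_m": 1.0e-3,
    "qh2_m": 1.0e-3,
}

_GLYCOLYSIS_TCA_REACTIONS: list[tuple[str, dict[str, int], str, int]] = [
    ("PGI", {"g6p_c": -1, "f6p_c": 1}, "upper_glycolysis", 1),
    ("PFK", {"f6p_c": -1, "atp_c": -1, "fdp_c": 1, "adp_c": 1}, "upper_glycolysis", 2),
    ("FBA", {"fdp_c": -1, "dhap_c": 1, "g3p_c": 1}, "upper_glycolysis", 3),
    ("TPI", {"dhap_c": -1, "g3p_c": 1}, "upper_glycolysis", 4),
    (
        "GAPD",
        {"g3p_c": -1, "nad_c": -1, "pi_c": -1, "13dpg_c": 1, "nadh_c": 1},
        "lower_glycolysis",
        1,
    ),
    ("PGK", {"13dpg_c": -1, "adp_c": -1, "3pg_c": 1, "atp_c": 1}, "lower_glycolysis", 2),
    ("PGM", {"3pg_c": -1, "2pg_c": 1}, "lower_glycolysis", 3),
    ("ENO", {"2pg_c": -1, "pep_c": 1}, "lower_glycolysis", 4),
    ("PYK", {"pep_c": -1, "adp_c": -1, "pyr_c": 1, "atp_c": 1}, "lower_glycolysis", 5),
    ("PYRt2m", {"pyr_c": -1, "pyr_m": 1}, "pyruvate_transport", 1),
    (
        "PDHm",
        {"pyr_m": -1, "coa_m": -1, "nad_c": -1, "accoa_m": 1, "co2_c": 1, "nadh_c": 1},
        "pdh",
        1,
    ),
    ("CSm", {"accoa_m": -1, "oaa_m": -1, "cit_m": 1, "coa_m": 1}, "tca", 1),
    ("ACONTa", {"cit_m": -1, "acon_m": 1}, "tca", 2),
    ("ACONTb", {"acon_m": -1, "icit_m": 1}, "tca", 3),
    (
        "ICDHxm",
        {"icit_m": -1, "nad_c": -1, "akg_m": 1, "co2_c": 1, "nadh_c": 1},
        "tca",
        4,
    ),
    (
        "AKGDm",
        {"akg_m": -1, "coa_m": -1, "nad_c": -1, "succoa_m": 1, "co2_c": 1, "nadh_c": 1},
        "tca",
        5,
    ),
    (
        "SUCOASm",
        {"succoa_m": -1, "adp_c": -1, "pi_c": -1, "succ_m": 1, "atp_c": 1, "coa_m": 1},
        "tca",
        6,
    ),
    ("SUCDm", {"succ_m": -1, "q_m": -1, "fum_m": 1, "qh2_m": 1}, "tca", 7),
    ("FUMm", {"fum_m": -1, "mal_m": 1}, "tca", 8),
    ("MDHm", {"mal_m": -1, "nad_c": -1, "oaa_m": 1, "nadh_c": 1}, "tca", 9),
]

_PPP_REACTIONS: list[tuple[str, dict[str, int], str, int]] = [
    (
        "G6PDH2r",
        {"g6p_c": -1, "nadp_c": -1, "6pgl_c": 1, "nadph_c": 1},
        "oxidative_ppp",
        1,
    ),
    ("PGL", {"6pgl_c": -1, "6pgc_c": 1}, "oxidative_ppp", 2),
    (
        "GND",
        {"6pgc_c": -1, "nadp_c": -1, "ru5p_c": 1, "co2_c": 1, "nadph_c": 1},
        "oxidative_ppp",
        3,
    ),
    ("RPE", {"ru5p_c": -1, "xu5p_c": 1}, "non_oxidative_ppp", 1),
    ("RPI", {"ru5p_c": -1, "r5p_c": 1}, "non_oxidative_ppp", 2),
    (
        "TKT1",
        {"xu5p_c": -1, "r5p_c": -1, "s7p_c": 1, "g3p_c": 1},
        "non_oxidative_ppp",
        3,
    ),
    (
        "TALA",
        {"s7p_c": -1, "g3p_c": -1, "e4p_c": 1, "f6p_c": 1},
        "non_oxidative_ppp",
        4,
    ),
    (
        "TKT2",
        {"xu5p_c": -1, "e4p_c": -1, "f6p_c": 1, "g3p_c": 1},
        "non_oxidative_ppp",
        5,
    ),
]

#: variable-species initial concentration (mol/L) for the central fixture
_INIT_VARIABLE = 1.0e-6


def make_central_metabolism(
    include_ppp: bool = False,
    nadp_nadph_ratio: float = 0.0175,
) -> tuple[NetworkModel, SystemState]:
    """Central-carbon fixture: 20 variable metabolites x 20 reactions
    (glycolysis + TCA); ``include_ppp`` adds the 8 pentose phosphate reactions
    and their 7 sugar intermediates plus the clamped NADP/NADPH pool.

    Returns the validated model and an initial state (variable species at
    1e-6 M, boundary species at their clamps).  Deterministic: no randomness.
    """
    if nadp_nadph_ratio <= 0:
        raise ValueError("nadp_nadph_ratio must be > 0")
    reactions = [
        Reaction(id=rid, stoich=dict(st), pathway_tag=tag, topological_rank=rank,
                 is_transport=(rid == "PYRt2m"))
        for rid, st, tag, rank in (
            _GLYCOLYSIS_TCA_REACTIONS + (_PPP_REACTIONS if include_ppp else [])
        )
    ]
    used = set()
    for r in reactions:
        used |= set(r.stoich)
    clamps = dict(_CLAMPS)
    if include_ppp:
        preset = NADP_NADPH_PRESETS.get(nadp_nadph_ratio)
        if preset is None:
            nadph = 1.0e-4
            preset = (nadp_nadph_ratio * nadph, nadph)
        clamps["nadp_c"], clamps["nadph_c"] = preset
    mets = []
    for met_id in _MU0:
        if met_id not in used:
            continue
        boundary = met_id in clamps
        mets.append(
            Metabolite(
                id=met_id,
                compartment=met_id.rsplit("_", 1)[-1],
                mu0=_MU0[met_id],
                is_boundary=boundary,
                conc0=clamps[met_id] if boundary else _INIT_VARIABLE,
            )
        )
    model = NetworkModel(
        metabolites=mets,
        reactions=reactions,
        medium=MediumConditions(dielectric=78.5, ionic_strength=0.25, pH=7.0),
    )
    state = SystemState(model, model.initial_concentrations())
    return model, state


def make_fixture(name: str, **kwargs):
    """Dispatch by fixture name (see ``FIXTURE_NAMES``).

    ``glycolysis`` is the 20x20 glycolysis+TCA network; ``glycolysis_ppp`` and
    ``central_metabolism`` both include the pentose phosphate pathway.
    """
    if name == "toy_pair":
        return make_toy_pair(**kwargs)
    if name == "chain":
        kwargs.setdefault("length", 3)
        return make_chain(**kwargs)
    if name == "glycolysis":
        return make_central_metabolism(include_ppp=False, **kwargs)
    if name in ("glycolysis_ppp", "central_metabolism"):
        return make_central_metabolism(include_ppp=True, **kwargs)
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


# ---------------------------------------------------------------------------
# printed loss-table records (regulation benchmark inputs)
# ---------------------------------------------------------------------------

_TABLE1 = [
    # (reaction, predicted product of concentrations, expected product)
    ("CSm", 4.85e-6, 1.00e-6),
    ("SUCOASm", 6.62e-9, 1.00e-9),
    ("ENO", 6.65e-1, 1.00e-3),
    ("PGM", 1.33, 1.00e-3),
    ("HEX1", 4.26e-2, 1.00e-6),
    ("PGI", 4.58e1, 1.00e-3),
    ("GAPD", 4.82e-2, 1.00e-6),
    ("PYRt2m", 8.43e2, 1.00e-3),
    ("PGK", 1.09, 1.00e-6),
    ("PYK", 5.84, 1.00e-6),
    ("PFK", 9.21e2, 1.00e-6),
    ("PDHm", 8.66, 1.00e-9),
]


def table1_records() -> list[LossRecord]:
    """The published central-metabolism loss-table inputs (predicted and
    expected product-of-concentration pairs for the 12 violating reactions),
    as records ready for the loss function and target selection."""
    return [
        LossRecord(reaction_id=rid, predicted_product=p, expected_product=e)
        for rid, p, e in _TABLE1
    ]


def table1_pathway_metadata() -> dict[str, tuple[str, int]]:
    """Pathway tag and topological rank for the loss-table reactions
    (including hexokinase, which sits upstream of the clamped G6P entry and is
    therefore not part of the dynamic fixture)."""
    return {
        "HEX1": ("glucose_uptake", 1),
        "PGI": ("upper_glycolysis", 1),
        "PFK": ("upper_glycolysis", 2),
        "GAPD": ("lower_glycolysis", 1),
        "PGK": ("lower_glycolysis", 2),
        "PGM": ("lower_glycolysis", 3),
        "ENO": ("lower_glycolysis", 4),
        "PYK": ("lower_glycolysis", 5),
        "PYRt2m": ("pyruvate_transport", 1),
        "PDHm": ("pdh", 1),
        "CSm": ("tca", 1),
        "SUCOASm": ("tca", 6),
    }
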