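"""Inference of post-translational regulation from predicted concentrations.

The thermodynamically optimal steady state of a mass-action model can predict
metabolite levels far above anything physiological (the model has no diffusion
limit).  The gap is put to work: for each reaction alpha with products i(alpha)
a loss

    L_alpha = ln( prod_i n_i_predicted^gamma / prod_i cap_i^gamma )

compares predicted product levels to expected caps (natural log; a per-product
rule of thumb of 1e-3 M unless a metabolite-specific cap is set).  L = 0 when
prediction matches expectation; L > 0 flags the reaction as a candidate site of
post-translational regulation.  Regulation is applied as a Hill-type enzyme
activity lambda in (0, 1] that throttles *both* directions of a reaction —
leaving its equilibrium constant untouched — and each rule's half-saturation
constant is tuned by bisection until the regulated steady state meets the caps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .netmodel import NetworkModel
from .maxent import OptimizerOptions, SteadyStateResult, optimize_to_steady_state
from .thermo import SystemState

__all__ = [
    "LossRecord",
    "RegulationRule",
    "TargetAssignment",
    "loss",
    "loss_table",
    "loss_frame",
    "select_regulation_targets",
    "hill_activity",
    "tune_regulation",
]


@dataclass
class LossRecord:
    """Loss-function entry for one reaction (mirrors the predicted/expected/L
    triple of a loss table)."""

    reaction_id: str
    predicted_product: float
    expected_product: float

    @property
    def L(self) -> float:
        return math.log(self.predicted_product / self.expected_product)

    @property
    def violation(self) -> bool:
        return self.L > 0


@dataclass
class RegulationRule:
    """Hill-equation activity attached to one reaction.

    mode "inhibition": lambda = 1 / (1 + (n/kd)^h)  (decreasing in modulator)
    mode "activation": lambda = (n/kd)^h / (1 + (n/kd)^h)  (increasing)

    lambda multiplies both the forward and the reverse rate, so the reaction's
    equilibrium constant — and any closed-system fixed point — is unchanged.
    """

    reaction_id: str
    modulator_id: str
    kd: float
    hill_n: float = 4.0
    mode: str = "inhibition"

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if self.mode not in ("inhibition", "activation"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class TargetAssignment:
    """User-designated modulator wiring for one regulation target."""

    reaction_id: str
    modulator_id: str
    mode: str = "inhibition"
    hill_n: float = 4.0


def loss(
    predicted_products: float | Sequence[float],
    expected_products: float | Sequence[float],
) -> float:
    """L = ln(prod predicted / prod expected); natural logarithm.

    Accepts scalars (already-multiplied products of concentrations) or
    sequences of per-product concentrations.
    """
    pred = np.atleast_1d(np.asarray(predicted_products, dtype=float))
    exp = np.atleast_1d(np.asarray(expected_products, dtype=float))
    if np.any(pred <= 0) or np.any(exp <= 0):
        raise ValueError("concentrations must be > 0")
    return float(np.sum(np.log(pred)) - np.sum(np.log(exp)))


def loss_table(result: SteadyStateResult, model: NetworkModel) -> list[LossRecord]:
    """Per-reaction loss records, sorted by L descending.

    Products are the positive-stoichiometry species (clamped species included);
    predicted is prod n_i^gamma over products, expected is prod cap_i^gamma
    over the same species, so a two-product reaction with 1e-3 M caps has an
    expected product of 1e-6.
    """
    conc = result.state.conc
    records = []
    for r in model.reactions:
        pred = 1.0
        exp = 1.0
        for met, coef in r.stoich.items():
            if coef > 0:
                i = model.metabolite_index(met)
                pred *= conc[i] ** coef
                exp *= model.metabolites[i].expected_cap ** coef
        records.append(
            LossRecord(reaction_id=r.id, predicted_product=pred, expected_product=exp)
        )
    records.sort(key=lambda rec: rec.L, reverse=True)
    return records


def loss_frame(records: Sequence[LossRecord]) -> pd.DataFrame:
    """Loss table as a TSV-ready frame (reaction, predicted, expected, L)."""
    return pd.DataFrame(
        {
            "reaction": [r.reaction_id for r in records],
            "predicted": [r.predicted_product for r in records],
            "expected": [r.expected_product for r in records],
            "L": [r.L for r in records],
        }
    )


def _pathway_meta(
    model_or_meta: NetworkModel | Mapping[str, tuple[str, int]], rxn_id: str
) -> tuple[str, int]:
    if isinstance(model_or_meta, NetworkModel):
        r = model_or_meta.get_reaction(rxn_id)
        return r.pathway_tag, r.topological_rank
    return model_or_meta.get(rxn_id, ("", 0))


def select_regulation_targets(
    records: Sequence[LossRecord],
    model: NetworkModel | Mapping[str, tuple[str, int]],
    max_targets: int,
) -> list[str]:
    """Parsimonious choice of reactions to regulate.

    Two principles: reactions are ranked by loss, highest first, and a
    candidate is dropped when an already-selected reaction lies upstream of it
    on the same linear pathway segment (same ``pathway_tag``, smaller
    ``topological_rank``) — throttling the upstream step is expected to relieve
    the downstream violation too.  ``model`` may be a full network or a plain
    mapping reaction_id -> (pathway_tag, topological_rank).  Returns at most
    ``max_targets`` reaction ids; empty when nothing violates.
    """
    candidates = sorted(
        (rec for rec in records if rec.L > 0), key=lambda rec: rec.L, reverse=True
    )
    selected: list[str] = []
    for rec in candidates:
        if len(selected) >= max_targets:
            break
        tag, rank = _pathway_meta(model, rec.reaction_id)
        absorbed = False
        if tag:
            for sel in selected:
                sel_tag, sel_rank = _pathway_meta(model, sel)
                if sel_tag == tag and sel_rank < rank:
                    absorbed = True
                    break
        if not absorbed:
            selected.append(rec.reaction_id)
    return selected


def hill_activity(rule: RegulationRule, modulator_conc: float) -> float:
    """Enzyme activity lambda in (0, 1] at the given modulator level.

    Half-saturation at the modulator level kd for any Hill coefficient;
    zero modulator gives lambda = 1 for inhibition and 0+ for activation.
    """
    if modulator_conc < 0:
        raise ValueError("modulator concentration must be >= 0")
    x = (modulator_conc / rule.kd) ** rule.hill_n
    if rule.mode == "inhibition":
        return 1.0 / (1.0 + x)
    return x / (1.0 + x)


@dataclass
class TuneDiagnostics:
    iterations: int
    final_losses: dict[str, float]
    converged: bool
    message: str = ""


def tune_regulation(
    model: NetworkModel,
    init: SystemState | None,
    options: OptimizerOptions | None,
    targets: Sequence[TargetAssignment],
    l_stop: float | Mapping[str, float] = 0.0,
    l_tol: float = 0.05,
    max_bisect: int = 60,
    max_passes: int = 3,
) -> tuple[list[RegulationRule], SteadyStateResult, TuneDiagnostics]:
    """Tune Hill kd values until each target reaction's loss is <= l_stop.

    For every target the modulator's kd is bisected on log10(kd) over
    [cap*1e-4, cap*1e4] (cap = the modulator's expected cap), re-optimizing the
    Marcelin steady state at each trial and exploiting the monotone response of
    the target's product levels to its activity.  Multiple targets are handled
    coordinate-wise, with ``max_passes`` sweeps.  Returns the final rules, the
    regulated steady state, and diagnostics (best-so-far on non-convergence —
    never a silent failure).

    ``l_stop`` may be a scalar or a per-reaction mapping (a mild positive
    tolerance is legitimate for highly soluble products).
    """
    options = options or OptimizerOptions()
    if init is None:
        init = SystemState(model, model.initial_concentrations())
    if not targets:
        result = optimize_to_steady_state(model, init, options)
        return [], result, TuneDiagnostics(0, {}, True, "no targets")

    def stop_for(rid: str) -> float:
        if isinstance(l_stop, Mapping):
            return l_stop.get(rid, 0.0)
        return l_stop

    rules: dict[str, RegulationRule] = {}
    for t in targets:
        cap = model.metabolites[model.metabolite_index(t.modulator_id)].expected_cap
        rules[t.reaction_id] = RegulationRule(
            reaction_id=t.reaction_id,
            modulator_id=t.modulator_id,
            kd=cap,  # midpoint start; bisection re-places it
            hill_n=t.hill_n,
            mode=t.mode,
        )

    def losses_at(rule_list: list[RegulationRule], warm: SystemState):
        res = optimize_to_steady_state(model, warm, options, rule_list)
        recs = {rec.reaction_id: rec.L for rec in loss_table(res, model)}
        return res, recs

    warm = init
    result, current = losses_at(list(rules.values()), warm)
    iters = 0
    for _pass in range(max_passes):
        all_ok = True
        for t in targets:
            target_stop = stop_for(t.reaction_id)
            if current[t.reaction_id] <= target_stop + l_tol:
                continue
            all_ok = False
            cap = model.metabolites[model.metabolite_index(t.modulator_id)].expected_cap
            lo, hi = math.log10(cap * 1e-4), math.log10(cap * 1e4)
            # inhibition: smaller kd -> stronger throttle -> lower L
            for _ in range(max_bisect):
                mid = 0.5 * (lo + hi)
                rules[t.reaction_id].kd = 10.0 ** mid
                result, current = losses_at(list(rules.values()), result.state)
                iters += 1
                L = current[t.reaction_id]
                if abs(L - target_stop) <= l_tol:
                    break
                overshoot = L > target_stop
                if rules[t.reaction_id].mode == "inhibition":
                    # still violating -> throttle harder (smaller kd)
                    hi = mid if overshoot else hi
                    lo = lo if overshoot else mid
                else:
                    lo = mid if overshoot else lo
                    hi = hi if overshoot else mid
        if all_ok:
            break

    final = {t.reaction_id: current[t.reaction_id] for t in targets}
    converged = all(final[t.reaction_id] <= stop_for(t.reaction_id) + l_tol for t in targets)
    msg = "" if converged else "tuning hit iteration limits; returning best-so-far"
    return (
        list(rules.values()),
        result,
        TuneDiagnostics(iterations=iters, final_losses=final, converged=converged, message=msg),
    )
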