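"""Four-step workflow orchestration with reproducible on-disk outputs.

Step 1  optimize      -> steady.json                (unregulated maxent state)
Step 2  infer-regulation -> loss_table.tsv, regulation.json
Step 3  fit-rates     -> regulated_steady.json, rates.json
Step 4  simulate      -> trajectory.tsv, circuit_report.tsv

plus manifest.json recording versions, options, seed and residuals.  Any stage
failure halts with a stage-tagged error; outputs written so far are retained.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .netmodel import NetworkModel, load_model
from .thermo import SystemState, thermo_frame
from .maxent import OptimizerOptions, SteadyStateResult, optimize_to_steady_state
from .regulation import (
    RegulationRule,
    TargetAssignment,
    loss_frame,
    loss_table,
    select_regulation_targets,
    tune_regulation,
)
from .kinetics import (
    estimate_relaxation_time,
    infer_rate_constants,
    simulate,
)
from .circuit import circuit_report

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    model_path: str | Path | None = None
    model: NetworkModel | None = None
    init: SystemState | None = None
    options: OptimizerOptions = field(default_factory=OptimizerOptions)
    #: explicit regulation targets; when None, targets are selected from the
    #: loss table (up to max_targets) and wired to ``modulator_map``
    targets: list[TargetAssignment] | None = None
    modulator_map: Mapping[str, str] = field(default_factory=dict)
    max_targets: int = 2
    l_stop: float | Mapping[str, float] = 0.0
    out_dir: str | Path = "mepnet_run"
    horizon_relaxations: float = 10.0
    n_samples: int = 101
    seed: int | None = None

    def resolve_model(self) -> NetworkModel:
        if self.model is not None:
            return self.model
        if self.model_path is None:
            raise PipelineError("config", "neither model nor model_path given")
        return load_model(Path(self.model_path))


def _state_doc(result: SteadyStateResult, model: NetworkModel) -> dict:
    return {
        "converged": bool(result.converged),
        "residual": result.residual,
        "thermo_residual": result.thermo_residual,
        "c": result.c,
        "concentrations_M": {
            m.id: float(c) for m, c in zip(model.metabolites, result.state.conc)
        },
        "net_flux": {
            r.id: float(f) for r, f in zip(model.reactions, result.net_flux)
        },
        "message": result.message,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute steps 1-4; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = config.resolve_model()
    init = config.init or SystemState(model, model.initial_concentrations())
    manifest: dict = {
        "mepnet_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "options": {
            "c": config.options.c,
            "steady_tol": config.options.steady_tol,
            "rtol": config.options.rtol,
            "atol": config.options.atol,
        },
        "stages": {},
    }

    # -- step 1: unregulated maximum-entropy-production optimization --------
    try:
        base = optimize_to_steady_state(model, init, config.options)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("optimize", str(exc)) from exc
    (out / "steady.json").write_text(json.dumps(_state_doc(base, model), indent=2))
    thermo_frame(base.thermo).to_csv(out / "thermo.tsv", sep="\t", index=False)
    manifest["stages"]["optimize"] = {
        "converged": base.converged,
        "residual": base.residual,
    }
    if not base.converged:
        raise PipelineError("optimize", f"no convergence: {base.message}")

    # -- step 2: regulation inference ---------------------------------------
    records = loss_table(base, model)
    loss_frame(records).to_csv(out / "loss_table.tsv", sep="\t", index=False)
    if config.targets is not None:
        targets = list(config.targets)
    else:
        chosen = select_regulation_targets(records, model, config.max_targets)
        missing = [rid for rid in chosen if rid not in config.modulator_map]
        if missing:
            raise PipelineError(
                "infer-regulation",
                f"no modulator assigned for selected targets: {missing} "
                "(modulator choice is user input, not inferred)",
            )
        targets = [
            TargetAssignment(reaction_id=rid, modulator_id=config.modulator_map[rid])
            for rid in chosen
        ]
    manifest["stages"]["infer-regulation"] = {
        "targets": [t.reaction_id for t in targets]
    }

    # -- step 3: re-optimize with regulation; infer rate constants ----------
    rules, regulated, diag = tune_regulation(
        model, init, config.options, targets, l_stop=config.l_stop
    )
    (out / "regulation.json").write_text(
        json.dumps(
            [
                {
                    "reaction_id": r.reaction_id,
                    "modulator_id": r.modulator_id,
                    "mode": r.mode,
                    "hill_n": r.hill_n,
                    "kd_M": r.kd,
                }
                for r in rules
            ],
            indent=2,
        )
    )
    (out / "regulated_steady.json").write_text(
        json.dumps(_state_doc(regulated, model), indent=2)
    )
    loss_frame(loss_table(regulated, model)).to_csv(
        out / "regulated_loss_table.tsv", sep="\t", index=False
    )
    if not regulated.converged:
        raise PipelineError("fit-rates", f"regulated state not converged: {regulated.message}")
    rates = infer_rate_constants(regulated, model, rules)
    (out / "rates.json").write_text(
        json.dumps(
            [
                {"reaction_id": rc.reaction_id, "k_fwd": rc.k_fwd, "k_rev": rc.k_rev}
                for rc in rates
            ],
            indent=2,
        )
    )
    manifest["stages"]["fit-rates"] = {
        "tuning_iterations": diag.iterations,
        "tuning_converged": diag.converged,
        "final_losses": diag.final_losses,
    }

    # -- step 4: full mass-action simulation + circuit report ---------------
    tau = estimate_relaxation_time(model, regulated.state, rates, rules)
    horizon = config.horizon_relaxations * tau if np.isfinite(tau) else 10.0
    try:
        traj = simulate(
            model,
            regulated.state,
            rates,
            rules,
            horizon=horizon,
            n_samples=config.n_samples,
        )
    except RuntimeError as exc:
        raise PipelineError("simulate", str(exc)) from exc
    import pandas as pd

    cols = {"t": traj.times}
    for i, m in enumerate(model.metabolites):
        cols[f"n_{m.id}"] = traj.states[i]
    for j, r in enumerate(model.reactions):
        cols[f"flux_{r.id}"] = traj.fluxes[j]
    pd.DataFrame(cols).to_csv(out / "trajectory.tsv", sep="\t", index=False)
    report = circuit_report(regulated, model)
    report.to_frame().to_csv(out / "circuit_report.tsv", sep="\t", index=False)
    var = ~model.boundary_mask
    drift = float(
        np.max(np.abs(traj.states[var, -1] / regulated.state.conc[var] - 1.0))
    )
    manifest["stages"]["simulate"] = {
        "relaxation_time": tau,
        "horizon": horizon,
        "fixed_point_drift": drift,
        "entropy_production_rate": report.total_entropy_production_rate,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
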