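"""Circuit characterization and pentose-phosphate cycling analysis.

Left: per-reaction power/resistance at the regulated optimum — the throttled
phosphofructokinase carries the same flux as its neighbours at a much larger
driving force, i.e. it acts as the pathway's potentiometer.  Right: exact
flux-balance stoichiometry of the fully recycling pentose phosphate pathway
(6 NADPH + 3 CO2 per glucose 6-phosphate, three oxidative passes), and the
kinetic response of the oxidative branch to the NADP/NADPH ratio.
"""

from mepnet import optimize_to_steady_state
from mepnet.circuit import circuit_report, pathway_yield
from mepnet.fixtures import make_central_metabolism
from mepnet.regulation import TargetAssignment, tune_regulation

model, init = make_central_metabolism(include_ppp=False)
rules, regulated, _ = tune_regulation(
    model, init, None, [TargetAssignment("PFK", "atp_c")]
)
report = circuit_report(regulated, model)
print("glycolysis circuit rows (affinity-convention resistance = A/flux):")
for rid in ("PGI", "PFK", "FBA", "GAPD", "PYK"):
    row = report.row(rid)
    print(f"  {rid:5s} flux={row.flux:8.3f} -dG={-row.dG:8.2f} kJ/mol "
          f"power={row.power:9.2f} R={row.resistance:8.3f}")
print(f"total entropy production rate: "
      f"{report.total_entropy_production_rate:.4g} kJ/(mol K) per time\n")

ppp_model, _ = make_central_metabolism(include_ppp=True)
y = pathway_yield(
    ppp_model, "g6p_c", exits=["g3p_c", "co2_c"],
    active_reactions=["G6PDH2r", "PGL", "GND", "RPE", "RPI",
                      "TKT1", "TALA", "TKT2", "PGI"],
    cycle_reaction="G6PDH2r",
)
print("full pentose recycling, per glucose 6-phosphate (exact rationals):")
print(f"  NADPH: {y.yield_of('nadph_c')}, CO2: {y.yield_of('co2_c')}, "
      f"G3P: {y.yield_of('g3p_c')}, oxidative passes: {y.cycle_count}")
print(f"  (PGI runs at {y.fluxes['PGI']}: hexose isomerase in reverse "
      "recycles fructose 6-phosphate)\n")

print("oxidative flux vs NADP/NADPH clamp ratio:")
for ratio in (0.0175, 1.0, 31.0):
    mp, sp = make_central_metabolism(include_ppp=True, nadp_nadph_ratio=ratio)
    res = optimize_to_steady_state(mp, sp)
    print(f"  ratio {ratio:7g}: oxidative flux {res.flux('G6PDH2r'):8.2f}, "
          f"upper-glycolysis flux {res.flux('PFK'):8.2f}")
print("The oxidative branch takes over as the NADP/NADPH ratio rises.")
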