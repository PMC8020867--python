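# Methods

## Model and assumptions

`mepnet` treats a metabolic network as `M` species × `Z` reversible summary
reactions with signed stoichiometry `γ_iα` and equilibrium constants
`K_α = exp(−Σ_i γ_iα μ°_i / RT)`. Concentrations are dimensionless activities
on a 1 mol/L standard state; `T = 298.15 K`, `R = 8.314×10⁻³ kJ/(mol·K)`, so
`RT = 2.4790 kJ/mol`. Standard chemical potentials arrive already adjusted for
the medium (dielectric, ionic strength, pH — recorded as metadata only); water
and protons are folded into `K`. Enzymes are not modeled explicitly
(no Michaelis–Menten saturation): each reaction is the summary of its
catalytic process, modulated at most by a multiplicative activity λ.

The central quantity is the reaction affinity `A_α/RT = ln K_α − ln Q_α`;
its exponential, the thermodynamic odds `K/Q`, equals the ratio of forward to
reverse unidirectional mass-action flux as an exact identity. All affinity
arithmetic is carried out in log space, because unregulated optima can span
tens of orders of magnitude in concentration.

## Maximum-entropy-production optimization

Setting every unidirectional relaxation rate to one shared constant `c` gives
the Marcelin dynamics

    dn_i/dt = c Σ_α γ_iα λ_α (e^{A_α/RT} − e^{−A_α/RT}),

whose trajectories descend the free energy
`G/RT = Σ_i n_i (μ°_i/RT + ln n_i − 1)` (convex in the concentrations) and,
under clamped boundary species, converge to the unique thermodynamically
optimal non-equilibrium steady state. `c` rescales time only; the steady state
is invariant to it, which is also why the entropy-production-maximizing state
and rate distribution coincide. A per-reaction `c_α` override hook exists but
is off by default; the shared-`c` assumption is the modeling core.

Numerically, the solver is pseudo-transient continuation:

* log-concentration integration of the variable species (boundary species are
  excluded from the state vector, so clamps hold to machine precision);
* a stiff implicit integrator (BDF by default; any stiff method meeting the
  tolerances is acceptable — method identity is not part of the contract) over
  geometrically growing time windows (10× per window, from 10⁻³/c up to
  `t_max` = 10¹²/c);
* once the scaled residual falls below 10⁻², a Newton solve of the algebraic
  system `S_var · ζ(ln n) = 0` polishes the state to machine precision.

Two deliberate numerical choices:

* **Steadiness criterion.** The spec-level idea "relative derivative
  `|dn_i/dt|/n_i` below 10⁻⁹" is not attainable in double precision for
  ultratrace species (a 10⁻¹² M intermediate would need its O(10)-magnitude
  flux sums to cancel to 10⁻²¹ absolute). The implemented criterion is the
  flux-imbalance residual `‖S_var·ζ̇‖∞ / max(gross turnover, c)`, a
  dimensionless relative measure with the relaxation constant as absolute
  floor (so closed systems, whose gross turnover itself vanishes at
  equilibrium, can converge). Default `steady_tol = 10⁻⁹`; the Newton polish
  typically leaves ~10⁻¹⁵.
* **Conservation awareness.** Closed pools among the variable species (e.g. a
  TCA backbone without anaplerotic reactions) make `S_var` rank-deficient.
  The Newton system swaps the dependent balance rows (chosen by QR with
  pivoting) for normalized conserved-total constraints anchored at the initial
  state, so the polish stays on the invariant manifold the ODE evolves in.
  Consequence worth knowing: for such networks the steady state depends on the
  initial conserved totals, which are part of the problem statement.

Non-convergence within `t_max` returns `converged=False` with the residual and
a diagnostic message — never a silent answer. Kinetic (`S·ζ̇`) and
thermodynamic (`S·(K⁺Q⁻ − K⁻Q⁺)·1`, activities folded in when regulation is
present) residuals are reported separately.

## Regulation inference

For each reaction the loss is the natural log of the ratio of the product of
predicted product-species concentrations (stoichiometric powers, clamped
species included) to the product of their expected caps. The default cap is
10⁻³ M per metabolite — the rule of thumb that physiological metabolite levels
rarely exceed millimolar — and is configurable per species, so a two-product
reaction carries an expected value of 10⁻⁶, a three-product one 10⁻⁹. The
natural-log convention is pinned by the printed benchmark triples the tests
reproduce (ln(9.21×10²/10⁻⁶) = 20.64; base-10 would give 8.96).

Target selection ranks violating reactions by loss, highest first, and drops a
candidate when an already-selected reaction sits upstream of it on the same
pathway segment (same tag, smaller topological rank). This reading — loss
ranking primary, upstream precedence as a redundancy pruner — is the design
choice that reproduces the canonical selection of the two highest-loss
reactions even when upstream neighbours also violate mildly; a strict
"upstream always wins within a pathway" rule would instead pick the mild
upstream violation and is rejected. The remaining ambiguity is inherent: the
loss function locates reactions to regulate but says nothing about mechanism,
so modulator assignments (which metabolite inhibits what) are user input.

Regulation is a Hill activity, inhibition `λ = 1/(1+(n/kd)^h)` or activation
`(n/kd)^h/(1+(n/kd)^h)`, applied to **both** directions so `K` and every
closed-system fixed point are unchanged. Default Hill coefficient 4
(cooperative ATP-style inhibition); only `kd` is tuned — by bisection on
log₁₀ kd over [cap·10⁻⁴, cap·10⁴], at most 60 evaluations per target and three
coordinate sweeps for multiple targets, each evaluation a warm-started
re-optimization. The stop criterion is `L ≤ L_stop` (+0.05 bisection
tolerance); `L_stop` defaults to 0 and may be set per reaction (a mildly
positive tolerance is legitimate for highly soluble products such as organic
acids). Unattainable targets (e.g. a clamped downstream species already above
its cap) terminate with best-so-far values and diagnostics.

## Rate constants and mass-action simulation

From the regulated optimum, `k_fwd = ζ̇/(λ Π_react n^{|γ|} (1 − Q/K))` and
`k_rev = k_fwd/K` (detailed balance / Haldane; the alternative of treating the
reverse constant as `c·K·k_fwd` is dimensionally inconsistent and rejected).
Because the Marcelin flux is `cλ(K/Q − Q/K)`, the quotient reduces to the
singularity-free closed form `k_fwd = c(1 + K/Q)/Π_react n^{|γ|}`, which is
also the continuous limit used for equilibrated branches (`k_fwd Π n → 2c` at
`Q → K`), preserving the Marcelin relaxation timescale there rather than
introducing an arbitrary zero-flux convention.

The mass-action ODEs with these constants have the regulated optimum as a
fixed point by construction; the simulator integrates them in log space (BDF,
`rtol 10⁻⁹`) and the relaxation-time estimator takes the slowest non-conserved
eigenmode of a finite-difference Jacobian. Inferred constants are optimal for
the simulated growth condition and are not comparable to in-vitro
Michaelis–Menten parameters.

## Circuit descriptors and yield analysis

Power `P_α = A_α ζ̇_α ≥ 0` at any maximum-entropy-production steady state;
resistance is reported with the affinity convention `R_α = A_α/ζ̇_α` (affinity
equals the free-energy change in magnitude at steady state; this keeps `R`
non-negative for forward flux), conductance its reciprocal, with an infinite
sentinel where `|ζ̇|` is numerically zero (below 10⁻⁹ of the flux scale).
None of this implies a linear flux–force relation: a regulated reaction
carries its neighbours' flux at a much larger driving force — a potentiometer,
not a resistor obeying a linear law. The entropy production rate is
`Σ_α A_α ζ̇_α / T`.

Pathway yields are solved as exact rational constrained flux balance (sympy):
unit net consumption of the designated input, free net production only at the
designated exits and boundary species, everything else balanced, on a stated
active-reaction support. Uniqueness on that support is verified (rank
reported otherwise), so integer yields are integer-exact and independent of
`c`, rate constants and regulation strength.

## Fixtures: what they emulate and what they do not

The central-carbon fixture reproduces the *shape* of a reduced fungal
central-metabolism model: 20 variable metabolites × 20 reactions — upper
glycolysis (PGI, PFK, FBA, TPI), lower glycolysis (GAPD…PYK), pyruvate
transport and dehydrogenase, and a nine-step TCA cycle — with BiGG-style
identifiers, glucose 6-phosphate clamped at 2 mM as the driving nutrient, CO₂
at 0.1 mM as the sink, and CoA/ATP/ADP/Pi/NAD(H) pools plus an equal-potential
respiratory redox shuttle clamped as boundaries. `include_ppp=True` adds the
eight pentose phosphate reactions, seven sugar intermediates and the clamped
NADP(H) pool, with presets for NADP/NADPH ratios of 0.0175, 1 and 31 (the low
and high pairs taken from published exponential-growth mass-spectrometry
estimates). Which species are variable versus clamped is this fixture's own
documented choice; hexokinase sits upstream of the clamped G6P entry and is
therefore present only in the printed benchmark records, not in the dynamic
network.

The chemical potentials are a frozen emulation table, chosen once so the
qualitative physiology holds — strongly exergonic PFK and PDH, near-neutral
isomerizations, PFK the largest unregulated loss, oxidative-PPP drive growing
with NADP/NADPH — and internally consistent with every `K`. They are **not**
literature formation energies, so absolute concentrations, fluxes and driving
forces from these fixtures are illustrative only. Everything the tests assert
quantitatively is potential-independent: printed loss-table arithmetic,
stoichiometric flux ratios (lower/TCA = 2× upper, forced by the aldolase
split), exact PPP yields, detailed-balance identities, and monotone scan
responses. The fixtures also idealize pooled cofactors across compartments and
omit anaplerosis (hence the conserved TCA pool set by the initial condition)
and all transport energetics except a neutral pyruvate carrier. Passing tests
therefore validate the method's mechanics and invariants, not organism-specific
numbers.

Problem sizes throughout (≤ 30 species, ≤ 28 reactions, three-point scans)
keep every steady-state solve under a couple of seconds; they are the sizes at
which the package's exactness claims (rational yields, machine-precision fixed
points) are meaningfully testable.

## Known limitations

* No diffusion, crowding or compartment-specific corrections: the unregulated
  optimum deliberately over-concentrates intermediates, which is precisely the
  signal the loss function consumes.
* Single shared `c`: mixing elementary and summary reactions at very different
  intrinsic timescales would need the per-reaction override and is untested.
* Regulated steady states need not be unique in principle (the Hill activity
  breaks convexity); warm-started continuation during tuning keeps the solver
  on one branch but no global search is attempted.
* Biomass formation, growth dilution and stochastic kinetics are out of scope.
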