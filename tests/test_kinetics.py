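"""Rate-constant inference, mass-action dynamics, and fixed-point consistency."""

import math

import numpy as np
import pytest

from mepnet.fixtures import make_chain, make_toy_pair
from mepnet.kinetics import (
    RateConstants,
    estimate_relaxation_time,
    infer_rate_constants,
    mass_action_rhs,
    simulate,
)
from mepnet.maxent import optimize_to_steady_state
from mepnet.thermo import SystemState, affinity, fluctuation_ratio


class TestInferRateConstants:
    def test_toy_hand_values(self):
        """A+B<=>C+D with K=2 at n=(1,1,1,1): flux = c(2 - 1/2) = 1.5c,
        k_fwd = 1.5c/(1*(1-1/2)) = 3c, k_rev = 1.5c."""
        m = make_toy_pair(K=2.0)
        from mepnet.maxent import evaluate_state

        res = evaluate_state(m, SystemState(m, np.ones(4)))
        # evaluate_state marks unsteady states as unconverged; inference wants
        # the flux decomposition anyway, so fake convergence for the identity
        res.converged = True
        rates = infer_rate_constants(res, m, c=1.0)
        rc = rates[0]
        assert rc.k_fwd == pytest.approx(3.0, rel=1e-12)
        assert rc.k_rev == pytest.approx(1.5, rel=1e-12)
        # mass-action net rate reproduces the Marcelin net flux
        assert rc.k_fwd * 1 * 1 - rc.k_rev * 1 * 1 == pytest.approx(1.5)

    def test_haldane_relation_on_fixture(self, glyc_tca, inferred_rates):
        model, _ = glyc_tca
        for rc in inferred_rates:
            K = model.get_reaction(rc.reaction_id).keq
            assert rc.k_fwd / rc.k_rev == pytest.approx(K, rel=1e-9)

    def test_equilibrated_branch_keeps_marcelin_timescale(self):
        """Zero-net-flux reactions get the continuous limit of the inference
        formula, k_fwd * prod_react n = 2c at equilibrium."""
        m = make_chain(2, [4.0])
        res = optimize_to_steady_state(m, SystemState(m, np.array([2.5, 2.5])))
        rates = infer_rate_constants(res, m, c=1.0)
        n_react = res.state.conc[0]
        assert rates[0].k_fwd * n_react == pytest.approx(2.0, rel=1e-4)

    def test_unconverged_input_rejected(self, glyc_tca):
        model, state = glyc_tca
        from mepnet.maxent import evaluate_state

        res = evaluate_state(model, state)
        assert not res.converged
        with pytest.raises(ValueError, match="converged"):
            infer_rate_constants(res, model)


class TestMassActionRhs:
    def test_hand_value(self):
        m = make_chain(2, [2.0])
        rates = [RateConstants("R1", k_fwd=2.0, k_rev=1.0)]
        s = SystemState(m, np.array([1.0, 1.0]))
        d = mass_action_rhs(m, s, rates)
        assert d[1] == pytest.approx(1.0)
        assert d[0] == pytest.approx(-1.0)

    def test_closed_moiety_conservation(self):
        m = make_toy_pair(K=2.0)
        rates = [RateConstants("R1", k_fwd=3.0, k_rev=1.5)]
        s = SystemState(m, np.array([0.5, 1.5, 2.0, 0.25]))
        d = mass_action_rhs(m, s, rates)
        assert d.sum() == pytest.approx(0.0, abs=1e-14)  # A+B+C+D total conserved

    def test_fixed_point_by_construction(self, glyc_tca, regulated, inferred_rates):
        model, _ = glyc_tca
        rules, result, _ = regulated
        d = mass_action_rhs(model, result.state, inferred_rates, rules)
        scale = np.max(np.abs(result.net_flux))
        assert np.max(np.abs(d)) / scale < 1e-8

    def test_thermodynamic_consistency_along_state(self):
        """Unidirectional mass-action rates obey fwd/rev = exp(A/RT) exactly."""
        m = make_chain(2, [2.0])
        rates = [RateConstants("R1", k_fwd=2.0, k_rev=1.0)]
        s = SystemState(m, np.array([0.7, 0.4]))
        fwd = rates[0].k_fwd * s.conc[0]
        rev = rates[0].k_rev * s.conc[1]
        th = affinity(s, m.reactions[0])
        assert fluctuation_ratio(fwd, rev) == pytest.approx(th.odds, rel=1e-12)


class TestSimulate:
    def test_flat_at_fixed_point(self, glyc_tca, regulated, inferred_rates):
        model, _ = glyc_tca
        rules, result, _ = regulated
        tau = estimate_relaxation_time(model, result.state, inferred_rates, rules)
        traj = simulate(model, result.state, inferred_rates, rules,
                        horizon=10 * tau, n_samples=11)
        var = ~model.boundary_mask
        drift = np.max(np.abs(traj.states[var, -1] / result.state.conc[var] - 1))
        assert drift < 1e-6

    def test_perturbation_returns_to_steady_state(self, glyc_tca, regulated,
                                                  inferred_rates):
        model, _ = glyc_tca
        rules, result, _ = regulated
        pert = result.state.conc.copy()
        pert[model.metabolite_index("fdp_c")] *= 1.1
        tau = estimate_relaxation_time(model, result.state, inferred_rates, rules)
        traj = simulate(model, SystemState(model, pert), inferred_rates, rules,
                        horizon=10 * tau, n_samples=21)
        var = ~model.boundary_mask
        dist = [
            np.max(np.abs(np.log(traj.states[var, k] / result.state.conc[var])))
            for k in range(len(traj.times))
        ]
        assert dist[-1] < 1e-3 * dist[0]

    def test_closed_pair_relaxes_to_K(self):
        m = make_chain(2, [4.0])
        rates = [RateConstants("R1", k_fwd=4.0, k_rev=1.0)]
        init = SystemState(m, np.array([4.0, 1.0]))
        traj = simulate(m, init, rates, horizon=20.0, n_samples=41)
        ratio = traj.states[1] / traj.states[0]
        assert ratio[-1] == pytest.approx(4.0, rel=1e-6)
        # monotone approach for the scalar relaxation
        assert all(b >= a - 1e-9 for a, b in zip(ratio, ratio[1:]))

    def test_boundary_constant_throughout(self, glyc_tca, regulated, inferred_rates):
        model, _ = glyc_tca
        rules, result, _ = regulated
        traj = simulate(model, result.state, inferred_rates, rules,
                        horizon=0.1, n_samples=5)
        b = model.boundary_mask
        for k in range(len(traj.times)):
            np.testing.assert_array_equal(traj.states[b, k], result.state.conc[b])

    def test_missing_rates_rejected(self, glyc_tca, regulated):
        model, _ = glyc_tca
        rules, result, _ = regulated
        with pytest.raises(ValueError, match="missing"):
            simulate(model, result.state, [RateConstants("PGI", 1.0, 1.0)], rules)


class TestCInvariance:
    def test_concentrations_invariant_fluxes_linear(self):
        m = make_chain(3, [2.0, 0.5], clamp_head=1.5, clamp_tail=0.2)
        from mepnet.maxent import OptimizerOptions

        res1 = optimize_to_steady_state(m, None, OptimizerOptions(c=1.0))
        res5 = optimize_to_steady_state(m, None, OptimizerOptions(c=5.0))
        np.testing.assert_allclose(res1.state.conc, res5.state.conc, rtol=1e-8)
        rates1 = infer_rate_constants(res1, m)
        rates5 = infer_rate_constants(res5, m)
        for a, b in zip(rates1, rates5):
            assert b.k_fwd == pytest.approx(5.0 * a.k_fwd, rel=1e-8)
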