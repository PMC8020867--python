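"""Loss function, target selection, Hill activities, and kd tuning."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mepnet.fixtures import (
    make_chain,
    make_toy_pair,
    table1_pathway_metadata,
    table1_records,
)
from mepnet.maxent import optimize_to_steady_state
from mepnet.regulation import (
    LossRecord,
    RegulationRule,
    TargetAssignment,
    hill_activity,
    loss,
    loss_table,
    select_regulation_targets,
    tune_regulation,
)
from mepnet.thermo import SystemState


class TestLoss:
    def test_agreement_gives_zero(self):
        assert loss([2e-4, 5e-5], [2e-4, 5e-5]) == pytest.approx(0.0)

    def test_natural_log_convention(self):
        assert loss(1.0, 1e-3) == pytest.approx(math.log(1e3), rel=1e-12)

    @pytest.mark.parametrize("pred,exp,L", [
        (9.21e2, 1.00e-6, 20.64),   # strongly violating two-product reaction
        (8.66, 1.00e-9, 22.88),     # three-product reaction
        (4.85e-6, 1.00e-6, 1.58),   # mild violation
    ])
    def test_published_loss_values(self, pred, exp, L):
        assert loss(pred, exp) == pytest.approx(L, abs=0.01)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            loss(0.0, 1e-3)


class TestLossTable:
    def test_all_at_caps_gives_zero_losses(self):
        m = make_chain(3, [1.0, 1.0], clamp_head=1e-3, clamp_tail=1e-3)
        res = optimize_to_steady_state(m)
        for rec in loss_table(res, m):
            assert rec.L == pytest.approx(0.0, abs=1e-6)

    def test_two_products_at_cap_each(self):
        # product of two 1e-3 M species against two 1e-3 M caps -> L = 0;
        # this is why multi-product rows carry 1e-6 / 1e-9 expected values
        assert loss([1e-3, 1e-3], [1e-3, 1e-3]) == pytest.approx(0.0)

    def test_single_molar_product_gives_ln_thousand(self, glyc_tca):
        model, _ = glyc_tca
        conc = model.initial_concentrations()
        conc[model.metabolite_index("fdp_c")] = 1.0  # cap is 1e-3
        from mepnet.maxent import evaluate_state

        res = evaluate_state(model, SystemState(model, conc))
        rec = next(r for r in loss_table(res, model) if r.reaction_id == "PFK")
        # PFK products: fdp (1 M vs 1e-3) and clamped adp (5.6e-4 vs 1e-3)
        expected = math.log(1.0 / 1e-3) + math.log(5.6e-4 / 1e-3)
        assert rec.L == pytest.approx(expected, rel=1e-9)


class TestSelectTargets:
    def test_published_records_give_pfk_and_pdh(self):
        sel = select_regulation_targets(
            table1_records(), table1_pathway_metadata(), max_targets=2
        )
        assert set(sel) == {"PFK", "PDHm"}
        assert sel == ["PDHm", "PFK"]  # loss-descending order

    def test_no_violations_gives_empty_list(self):
        recs = [LossRecord("R1", 1e-6, 1e-3), LossRecord("R2", 1e-9, 1e-6)]
        assert select_regulation_targets(recs, {}, max_targets=5) == []

    def test_upstream_absorbs_downstream_on_same_segment(self):
        meta = {"UP": ("seg", 1), "DOWN": ("seg", 2)}
        recs = [LossRecord("UP", 1.0, 1e-3), LossRecord("DOWN", 1e-1, 1e-3)]
        # UP ranks first (higher L) and absorbs DOWN
        assert select_regulation_targets(recs, meta, max_targets=5) == ["UP"]

    def test_max_targets_cap(self):
        recs = table1_records()
        sel = select_regulation_targets(recs, table1_pathway_metadata(), 1)
        assert sel == ["PDHm"]


class TestHillActivity:
    def test_zero_inhibitor_full_activity(self):
        rule = RegulationRule("R", "X", kd=1e-3, hill_n=2, mode="inhibition")
        assert hill_activity(rule, 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("hill_n", [1.0, 2.0, 4.0, 7.0])
    def test_half_saturation_at_kd(self, hill_n):
        for mode in ("inhibition", "activation"):
            rule = RegulationRule("R", "X", kd=2e-4, hill_n=hill_n, mode=mode)
            assert hill_activity(rule, 2e-4) == pytest.approx(0.5)

    def test_cooperative_inhibition_hand_value(self):
        rule = RegulationRule("R", "X", kd=1e-3, hill_n=2, mode="inhibition")
        assert hill_activity(rule, 3e-3) == pytest.approx(0.1)

    @given(n=st.floats(min_value=1e-12, max_value=1e3),
           hill_n=st.floats(min_value=1, max_value=8))
    def test_bounds_and_monotonicity(self, n, hill_n):
        rule = RegulationRule("R", "X", kd=1e-3, hill_n=hill_n, mode="inhibition")
        lam = hill_activity(rule, n)
        assert 0.0 < lam <= 1.0
        assert hill_activity(rule, n * 2) <= lam

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RegulationRule("R", "X", kd=-1.0)
        with pytest.raises(ValueError):
            RegulationRule("R", "X", kd=1e-3, hill_n=0.5)


class TestRegulationSemantics:
    def test_regulation_preserves_closed_fixed_point(self):
        """lambda on both directions leaves the equilibrium unchanged."""
        m = make_toy_pair(K=2.0)
        rule = RegulationRule("R1", "A", kd=1e-1, hill_n=2, mode="inhibition")
        res_plain = optimize_to_steady_state(m)
        res_reg = optimize_to_steady_state(m, regulation=[rule])
        np.testing.assert_allclose(res_reg.state.conc, res_plain.state.conc, rtol=1e-6)

    def test_throttling_reduces_flux_at_matched_boundaries(self):
        m = make_chain(3, [1.0, 1.0], clamp_head=2.0, clamp_tail=0.1)
        res_plain = optimize_to_steady_state(m)
        rule = RegulationRule("R1", "A1", kd=1e-1, hill_n=2, mode="inhibition")
        res_reg = optimize_to_steady_state(m, regulation=[rule])
        assert res_reg.converged
        assert 0 < res_reg.flux("R1") < res_plain.flux("R1")


class TestTuneRegulation:
    def test_empty_targets_returns_unregulated_state(self, glyc_tca):
        model, state = glyc_tca
        rules, result, diag = tune_regulation(model, state, None, [])
        assert rules == []
        assert result.converged and diag.converged

    def test_monotone_bisection_reaches_stop_loss(self):
        """On a chain whose violating product responds monotonically to the
        activity, the loop lands within tolerance of L_stop."""
        m = make_chain(3, [1.0, 1.0], clamp_head=2.0, clamp_tail=1e-4)
        # unregulated middle: sqrt-ish level ~1.4e-2 >> 1e-3 cap
        base = optimize_to_steady_state(m)
        rec = next(r for r in loss_table(base, m) if r.reaction_id == "R1")
        assert rec.L > 1.0
        rules, result, diag = tune_regulation(
            m, None, None, [TargetAssignment("R1", "A2", hill_n=2)]
        )
        final = next(r for r in loss_table(result, m) if r.reaction_id == "R1")
        assert diag.converged
        assert final.L <= 0.05
        assert final.L == pytest.approx(0.0, abs=0.06)  # bisection stops near L_stop

    def test_unattainable_target_reports_best_so_far(self):
        # clamped tail (0.1 M) exceeds the cap, so L cannot reach 0
        m = make_chain(3, [1.0, 1.0], clamp_head=2.0, clamp_tail=0.1)
        rules, result, diag = tune_regulation(
            m, None, None, [TargetAssignment("R1", "A2", hill_n=2)],
            max_bisect=20, max_passes=1,
        )
        assert not diag.converged
        assert diag.message
        assert diag.final_losses["R1"] >= math.log(0.1 / 1e-3) - 0.05

    def test_regulated_fixture_meets_caps(self, glyc_tca, regulated):
        """After tuning the PFK throttle, no reaction violates its caps beyond
        a hair of tolerance, and all variable concentrations respect the rule
        of thumb."""
        model, _ = glyc_tca
        rules, result, diag = regulated
        assert diag.converged
        violations = [r for r in loss_table(result, model) if r.L > 0.05]
        assert len(violations) <= 1
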