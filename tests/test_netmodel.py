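"""Model construction, K/mu0 duality, validation, and JSON round-trips."""

import math

import numpy as np
import pytest

from mepnet.netmodel import (
    Metabolite,
    ModelValidationError,
    NetworkModel,
    Reaction,
    load_model,
    save_model,
    stoichiometric_matrix,
)
from mepnet.fixtures import make_central_metabolism, make_toy_pair

RT = 8.314e-3 * 298.15


def simple_model(mu_a=0.0, mu_b=0.0, keq=None):
    return NetworkModel(
        metabolites=[Metabolite(id="A", mu0=mu_a), Metabolite(id="B", mu0=mu_b)],
        reactions=[Reaction(id="R", stoich={"A": -1, "B": 1}, keq=keq)],
    )


class TestKeqMuDuality:
    def test_equal_potentials_force_K_of_one(self):
        assert simple_model().reactions[0].keq == pytest.approx(1.0)

    def test_rt_ln_ten_gap_gives_K_ten(self):
        # mu_A - mu_B = RT ln 10  =>  K = exp(dmu/RT) = 10
        m = simple_model(mu_a=RT * math.log(10), mu_b=0.0)
        assert m.reactions[0].keq == pytest.approx(10.0, rel=1e-12)

    def test_consistent_keq_and_mu_accepted(self):
        m = simple_model(mu_a=RT * math.log(10), keq=10.0)
        assert m.reactions[0].keq == pytest.approx(10.0)

    def test_inconsistent_keq_and_mu_rejected(self):
        with pytest.raises(ModelValidationError, match="inconsistent"):
            simple_model(mu_a=RT * math.log(10), keq=2.0)

    def test_missing_thermodynamics_rejected(self):
        with pytest.raises(ModelValidationError, match="neither keq"):
            NetworkModel(
                metabolites=[Metabolite(id="A"), Metabolite(id="B")],
                reactions=[Reaction(id="R", stoich={"A": -1, "B": 1})],
            )


class TestValidation:
    def test_duplicate_metabolite_ids(self):
        with pytest.raises(ModelValidationError, match="duplicate metabolite"):
            NetworkModel(
                metabolites=[Metabolite(id="A", mu0=0.0), Metabolite(id="A", mu0=0.0)],
                reactions=[Reaction(id="R", stoich={"A": -1, "A": 1}, keq=1.0)],
            )

    def test_unknown_metabolite_reference(self):
        with pytest.raises(ModelValidationError, match="unknown metabolites"):
            NetworkModel(
                metabolites=[Metabolite(id="A", mu0=0.0), Metabolite(id="B", mu0=0.0)],
                reactions=[Reaction(id="R", stoich={"A": -1, "X": 1}, keq=1.0)],
            )

    def test_orphan_metabolite_is_zero_row(self):
        with pytest.raises(ModelValidationError, match="no reaction"):
            NetworkModel(
                metabolites=[
                    Metabolite(id="A", mu0=0.0),
                    Metabolite(id="B", mu0=0.0),
                    Metabolite(id="Z", mu0=0.0),
                ],
                reactions=[Reaction(id="R", stoich={"A": -1, "B": 1}, keq=1.0)],
            )

    def test_one_sided_reaction_rejected(self):
        with pytest.raises(ModelValidationError, match="reactants and products"):
            NetworkModel(
                metabolites=[Metabolite(id="A", mu0=0.0), Metabolite(id="B", mu0=0.0)],
                reactions=[
                    Reaction(id="R", stoich={"A": -1, "B": 1}, keq=1.0),
                    Reaction(id="R2", stoich={"A": -1, "B": -1}, keq=1.0),
                ],
            )

    def test_boundary_needs_clamp_value(self):
        with pytest.raises(ModelValidationError, match="clamped conc0"):
            Metabolite(id="A", is_boundary=True)

    def test_expected_cap_positive(self):
        with pytest.raises(ModelValidationError, match="expected_cap"):
            Metabolite(id="A", expected_cap=0.0)


class TestStoichiometricMatrix:
    def test_two_substrate_column(self):
        m = make_toy_pair(K=2.0)
        S = stoichiometric_matrix(m)
        assert S[:, 0].tolist() == [-1, -1, 1, 1]

    def test_aldolase_style_split_column(self):
        m = NetworkModel(
            metabolites=[
                Metabolite(id="f16bp", mu0=0.0),
                Metabolite(id="gap", mu0=0.0),
            ],
            reactions=[Reaction(id="FBA", stoich={"f16bp": -1, "gap": 2})],
        )
        assert stoichiometric_matrix(m)[:, 0].tolist() == [-1, 2]

    def test_central_fixture_has_twenty_by_twenty_variable_block(self):
        model, _ = make_central_metabolism(include_ppp=False)
        assert model.n_reactions == 20
        assert int((~model.boundary_mask).sum()) == 20

    def test_rows_and_columns_follow_model_order(self):
        model, _ = make_central_metabolism(include_ppp=False)
        S = stoichiometric_matrix(model)
        j = model.reaction_index("PFK")
        assert S[model.metabolite_index("f6p_c"), j] == -1
        assert S[model.metabolite_index("fdp_c"), j] == 1


class TestRoundTrip:
    @pytest.mark.parametrize("make", [
        lambda: make_toy_pair(K=2.0),
        lambda: make_central_metabolism(include_ppp=True)[0],
    ])
    def test_save_load_identity(self, make, tmp_path):
        model = make()
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert [m.id for m in back.metabolites] == [m.id for m in model.metabolites]
        assert [r.id for r in back.reactions] == [r.id for r in model.reactions]
        np.testing.assert_array_equal(back.S, model.S)
        np.testing.assert_allclose(back.keq_vector, model.keq_vector, rtol=0)
        for a, b in zip(model.metabolites, back.metabolites):
            assert a.mu0 == b.mu0
            assert a.is_boundary == b.is_boundary
            assert a.conc0 == b.conc0
            assert a.expected_cap == b.expected_cap
        for a, b in zip(model.reactions, back.reactions):
            assert a.stoich == b.stoich
            assert a.pathway_tag == b.pathway_tag
            assert a.topological_rank == b.topological_rank
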