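"""Model definition, dilution-row assembly, fixed-mu reduction, JSON I/O."""
import json

import pytest
from gmpy2 import mpq

from quadme.arith import INF, rat, rat_to_str
from quadme.model_core import (Annotation, DilutionConstants, DilutionRow,
                               MEModelSpec, ModelValidationError,
                               assemble_general_form, build_dilution_rows,
                               fix_mu, model_from_json_dict,
                               model_to_json_dict, models_equal,
                               mu_level_set_residual, read_model_json,
                               write_model_json)
from quadme.synthetic import (make_analytic_model, make_coupled_complex_model,
                              make_multiscale_model, make_two_pathway_model)

ALL_FIXTURES = [make_analytic_model, make_coupled_complex_model,
                make_two_pathway_model,
                lambda: make_multiscale_model(seed=7)]


def tiny_machinery_model():
    """One translation reaction + ribosome/enzyme dilution reactions."""
    rids = ["v_tr", "v_dil_ribo", "v_dil_enz", "v_usage"]
    anns = {
        "v_tr": Annotation("translation", gene="gX", peptide_length=mpq(300)),
        "v_dil_ribo": Annotation("dilution", species="ribosome"),
        "v_dil_enz": Annotation("dilution", species="enzA"),
        "v_usage": Annotation("enzyme_usage"),
    }
    return MEModelSpec(rids, [], {}, [mpq(0)] * 4, [INF] * 4,
                       annotations=anns)


class TestBuildDilutionRows:
    def test_ribosome_row_coefficients(self):
        # l_p=300, c_ribo=3, kappa_tau=4, r0=0.5:
        # b[v_tr] = -300*0.5/3 = -50, c[v_tr] = 300/(3*4) = 25
        model = tiny_machinery_model()
        consts = DilutionConstants(c_ribo=3, kappa_tau=4, r0=rat("0.5"))
        rows = build_dilution_rows(model, consts)
        ribo = [r for r in rows if r.family == "ribosome"]
        assert len(ribo) == 1
        assert ribo[0].b == {"v_dil_ribo": 1, "v_tr": -50}
        assert ribo[0].c == {"v_tr": 25}
        assert ribo[0].sense == "ge"

    def test_enzyme_row_is_inverse_keff(self):
        model = tiny_machinery_model()
        consts = DilutionConstants(k_eff={("enzA", "v_usage"): 100})
        rows = build_dilution_rows(model, consts)
        enz = [r for r in rows if r.family == "enzyme"]
        assert len(enz) == 1
        assert enz[0].b == {"v_dil_enz": 1}
        assert enz[0].c == {"v_usage": mpq(1, 100)}

    def test_empty_component_sets_give_no_rows(self):
        model = MEModelSpec(["a"], [], {}, [mpq(0)], [INF])
        assert build_dilution_rows(model, DilutionConstants()) == []

    def test_unknown_usage_reaction_is_reported(self):
        model = tiny_machinery_model()
        consts = DilutionConstants(k_eff={("enzA", "nope"): 10})
        with pytest.raises(ModelValidationError, match="nope"):
            build_dilution_rows(model, consts)

    def test_nonpositive_constant_rejected(self):
        with pytest.raises(ModelValidationError, match="c_ribo"):
            build_dilution_rows(tiny_machinery_model(),
                                DilutionConstants(c_ribo=0))


class TestGeneralForm:
    def test_no_dilution_rows_empty_matrices(self, analytic_model):
        model = MEModelSpec(["a", "b"], ["m"], {(0, 0): 1, (0, 1): -1},
                            [mpq(0)] * 2, [INF] * 2)
        gf = assemble_general_form(model)
        assert gf.n_dilution == 0 and gf.Bmat == {} and gf.Cmat == {}

    def test_round_trip_rows(self):
        rows = [DilutionRow({"r0": mpq(2)}, {"r1": mpq(3)}, "ge", "generic", "a"),
                DilutionRow({"r4": mpq(1)}, {"r2": mpq(1, 7)}, "eq", "generic", "b")]
        model = MEModelSpec([f"r{j}" for j in range(5)], [], {},
                            [mpq(0)] * 5, [INF] * 5, dilution_rows=rows)
        gf = assemble_general_form(model)
        assert gf.n_dilution == 2 and gf.n_reactions == 5
        assert gf.Bmat == {(0, 0): 2, (1, 4): 1}
        assert gf.Cmat == {(0, 1): 3, (1, 2): mpq(1, 7)}
        assert gf.senses == ["ge", "eq"]

    def test_analytic_fixture_enzyme_coefficient(self):
        model = make_analytic_model(k_eff=250)
        gf = assemble_general_form(model)
        j_up = model.rxn_index("uptake")
        assert gf.Cmat[(0, j_up)] == mpq(1, 250)


class TestFixMu:
    def test_substitution_of_ge_row(self):
        row = DilutionRow({"x": mpq(1)}, {"y": mpq(2)}, "ge")
        model = MEModelSpec(["x", "y"], [], {}, [mpq(0)] * 2, [INF] * 2,
                            dilution_rows=[row])
        lp = fix_mu(model, rat("0.5"))
        assert lp.cols[0] == {0: 1}
        assert lp.cols[1] == {0: -1}
        assert lp.row_senses == ["ge"]

    def test_no_dilution_rows_is_plain_fba(self, analytic_model):
        model = MEModelSpec(analytic_model.reaction_ids,
                            analytic_model.metabolite_ids,
                            dict(analytic_model.S),
                            list(analytic_model.v_lower),
                            list(analytic_model.v_upper),
                            growth_reaction=None)
        for mu in (0, rat("0.7")):
            lp = fix_mu(model, mu)
            assert lp.n_rows == model.n_metabolites
            assert all(s == "eq" for s in lp.row_senses)

    def test_negative_mu_rejected(self, analytic_model):
        with pytest.raises(ValueError):
            fix_mu(analytic_model, -1)

    def test_sparsity_pattern_independent_of_mu(self, coupled_model):
        lp1 = fix_mu(coupled_model, rat("0.3"))
        lp2 = fix_mu(coupled_model, rat("0.6"))
        pat1 = [set(c) for c in lp1.cols]
        pat2 = [set(c) for c in lp2.cols]
        assert pat1 == pat2
        # coefficients differ only in dilution rows
        m_met = coupled_model.n_metabolites
        for c1, c2 in zip(lp1.cols, lp2.cols):
            for i in c1:
                if i < m_met:
                    assert c1[i] == c2[i]

    @pytest.mark.parametrize("make", ALL_FIXTURES)
    def test_exact_substitution_matches_general_form(self, make):
        """fix_mu equals per-row b - mu*c substitution in exact rationals."""
        model = make()
        mu = mpq(3, 7)
        gf = assemble_general_form(model)
        lp = fix_mu(model, mu)
        m_met = model.n_metabolites
        for k in range(gf.n_dilution):
            for j in range(gf.n_reactions):
                want = gf.Bmat.get((k, j), mpq(0)) - mu * gf.Cmat.get((k, j), mpq(0))
                got = lp.cols[j].get(m_met + k, mpq(0))
                assert got == want


class TestLevelSetResidual:
    def test_zero_vector_gives_zero_residuals(self, analytic_model):
        res = mu_level_set_residual(analytic_model, rat("0.4"),
                                    [0] * analytic_model.n_reactions)
        assert res == [0]

    def test_eq_row_ratio_definition(self):
        # b'v = 3, c'v = 2, mu = 1.5 -> residual 0
        row = DilutionRow({"x": mpq(3)}, {"x": mpq(2)}, "eq")
        model = MEModelSpec(["x"], [], {}, [mpq(0)], [INF], dilution_rows=[row])
        assert mu_level_set_residual(model, rat("1.5"), [mpq(1)]) == [0]

    def test_dimension_mismatch(self, analytic_model):
        with pytest.raises(ValueError):
            mu_level_set_residual(analytic_model, 0, [1, 2])

    def test_against_dense_recomputation(self, ctx):
        import numpy as np
        model = make_multiscale_model(seed=3)
        rng = np.random.default_rng(11)
        v = [rat(str(round(x, 6))) for x in rng.uniform(0, 5, model.n_reactions)]
        mu = mpq(1, 3)
        res = mu_level_set_residual(model, mu, v)
        n = model.n_reactions
        for k, row in enumerate(model.dilution_rows):
            bvec = [row.b.get(rid, mpq(0)) for rid in model.reaction_ids]
            cvec = [row.c.get(rid, mpq(0)) for rid in model.reaction_ids]
            dense = sum(bvec[j] * v[j] for j in range(n)) \
                - mu * sum(cvec[j] * v[j] for j in range(n))
            assert res[k] == dense  # exact rational agreement


class TestJsonRoundTrip:
    @pytest.mark.parametrize("make", ALL_FIXTURES)
    def test_round_trip_every_fixture(self, make, tmp_path):
        model = make()
        path = tmp_path / "m.json"
        write_model_json(model, path)
        back = read_model_json(path)
        assert models_equal(model, back)

    def test_missing_bounds_rejected(self, analytic_model):
        doc = model_to_json_dict(analytic_model)
        del doc["reactions"][0]["lb"]
        with pytest.raises(ModelValidationError, match="lb"):
            model_from_json_dict(doc)

    def test_missing_section_rejected(self, analytic_model):
        doc = model_to_json_dict(analytic_model)
        del doc["S"]
        with pytest.raises(ModelValidationError, match="S"):
            model_from_json_dict(doc)

    def test_tiny_coefficient_survives(self, tmp_path):
        model = MEModelSpec(["a", "b"], ["m"],
                            {(0, 0): rat("1e-15"), (0, 1): mpq(-1)},
                            [mpq(0)] * 2, [INF] * 2)
        path = tmp_path / "m.json"
        write_model_json(model, path)
        back = read_model_json(path)
        assert back.S[(0, 0)] == mpq(1, 10 ** 15)

    def test_nondecimal_rational_survives(self):
        assert rat(rat_to_str(mpq(1, 3))) == mpq(1, 3)
        assert rat_to_str(rat("9.35e-14")) == "0.0000000000000935"


class TestValidation:
    def test_duplicate_reaction_ids(self):
        with pytest.raises(ModelValidationError, match="duplicate"):
            MEModelSpec(["a", "a"], [], {}, [0, 0], [1, 1])

    def test_crossed_bounds(self):
        with pytest.raises(ModelValidationError, match="v_lower"):
            MEModelSpec(["a"], [], {}, [2], [1])

    def test_dilution_row_unknown_reaction(self):
        row = DilutionRow({"zz": mpq(1)}, {}, "ge")
        with pytest.raises(ModelValidationError, match="zz"):
            MEModelSpec(["a"], [], {}, [0], [1], dilution_rows=[row])

    def test_growth_reaction_negative_lower_bound(self):
        with pytest.raises(ModelValidationError, match="growth"):
            MEModelSpec(["g"], [], {}, [-1], [1], growth_reaction="g")
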