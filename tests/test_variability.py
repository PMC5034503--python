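"""Flux variability, knockout screening, magnitude accounting."""
import math

import pytest
from gmpy2 import mpq

from quadme.arith import INF, rat
from quadme.model_core import MEModelSpec
from quadme.nlp_solve import solve_me
from quadme.synthetic import (make_analytic_model, make_coupled_complex_model,
                              make_two_pathway_model)
from quadme.variability import (VariabilityError, flux_magnitude_summary,
                                knockout_screen, vary_me)


@pytest.fixture(scope="module")
def coupled():
    model = make_coupled_complex_model()
    from quadme.arith import ArithmeticContext
    ctx = ArithmeticContext.quad()
    return model, solve_me(model, ctx=ctx), ctx


class TestVaryMe:
    def test_two_lps_per_reaction(self, coupled):
        model, nlp, ctx = coupled
        res = vary_me(model, 0.5, ctx=ctx, nlp_result=nlp)
        assert res.lp_count == 2 * model.n_reactions

    def test_unconstrained_reaction_spans_its_bounds(self, ctx):
        model = MEModelSpec(["free", "g"], [], {}, [mpq(-5), mpq(0)],
                            [mpq(5), mpq(1)], growth_reaction="g")
        nlp = solve_me(model, ctx=ctx)
        res = vary_me(model, 0.5, reactions=["free"], ctx=ctx, nlp_result=nlp)
        lo, hi = res.ranges["free"]
        assert float(lo) == -5 and float(hi) == 5

    def test_no_crossing_anywhere(self, coupled, ctx):
        model, nlp, ctx = coupled
        for frac in (0.25, 1.0):
            res = vary_me(model, frac, ctx=ctx, nlp_result=nlp)
            for rid, (lo, hi) in res.ranges.items():
                assert float(lo) <= float(hi) + ctx.feas_tol

    def test_coupled_subunits_have_equal_ranges(self, coupled):
        """Two subunits whose only sink is one 1:1 complex: equal FVA."""
        model, nlp, ctx = coupled
        res = vary_me(model, 0.5, ctx=ctx, nlp_result=nlp)
        a = res.ranges["translation_su1"]
        b = res.ranges["translation_su2"]
        assert abs(float(a[0] - b[0])) <= 1e-12
        assert abs(float(a[1] - b[1])) <= 1e-12

    def test_warm_equals_cold_with_fewer_pivots(self, coupled):
        model, nlp, ctx = coupled
        warm = vary_me(model, 0.5, ctx=ctx, warm=True, nlp_result=nlp)
        cold = vary_me(model, 0.5, ctx=ctx, warm=False, nlp_result=nlp)
        for rid in warm.ranges:
            assert abs(float(warm.ranges[rid][0] - cold.ranges[rid][0])) <= 1e-12
            assert abs(float(warm.ranges[rid][1] - cold.ranges[rid][1])) <= 1e-12
        assert warm.iterations_total < cold.iterations_total
        assert warm.warm_start_hits > 0 and cold.warm_start_hits == 0

    def test_zero_variability_at_maximal_growth(self, coupled):
        """A unique optimal proteome leaves no slack in translation."""
        model, nlp, ctx = coupled
        res = vary_me(model, 1.0, ctx=ctx, nlp_result=nlp)
        for rid in ("translation_su1", "translation_su2"):
            lo, hi = res.ranges[rid]
            assert abs(float(hi - lo)) <= 1e-10

    def test_intervals_nest_with_growth_rate(self, coupled):
        """Lower growth leaves wider flux ranges (monotone dilution slack)."""
        model, nlp, ctx = coupled
        half = vary_me(model, 0.5, ctx=ctx, nlp_result=nlp)
        full = vary_me(model, 1.0, ctx=ctx, nlp_result=nlp)
        for rid in ("uptake", "translation_su1", "translation_su2",
                    "complex_formation"):
            h, f = half.ranges[rid], full.ranges[rid]
            assert float(h[0]) <= float(f[0]) + 1e-12
            assert float(f[1]) <= float(h[1]) + 1e-12

    def test_excessive_fraction_rejected(self, coupled):
        model, nlp, ctx = coupled
        with pytest.raises(VariabilityError):
            vary_me(model, 1.5, ctx=ctx, nlp_result=nlp)


class TestKnockoutScreen:
    def test_essential_enzyme_in_analytic_fixture(self, analytic_model, ctx):
        nlp = solve_me(analytic_model, ctx=ctx)
        res = knockout_screen(analytic_model, ["enz"],
                              rat(nlp.mu_star) / 2, ctx=ctx)
        assert res.verdicts == {"enz": "essential"}
        assert res.lp_count == 1

    def test_redundant_pathway_is_nonessential(self, two_pathway_model, ctx):
        nlp = solve_me(two_pathway_model, ctx=ctx)
        res = knockout_screen(two_pathway_model, ["g0", "g1", "g2"],
                              rat(nlp.mu_star) / 2, ctx=ctx)
        assert res.verdicts["g0"] == "essential"       # uptake enzyme
        assert res.verdicts["g1"] == "nonessential"    # pathway 1 of 2
        assert res.verdicts["g2"] == "nonessential"
        assert res.lp_count == 3

    def test_one_lp_per_gene(self, two_pathway_model, ctx):
        nlp = solve_me(two_pathway_model, ctx=ctx)
        res = knockout_screen(two_pathway_model, ["g1", "g2"],
                              rat(nlp.mu_star) / 2, ctx=ctx)
        assert res.lp_count == 2

    def test_empty_gene_list(self, analytic_model, ctx):
        res = knockout_screen(analytic_model, [], rat("0.1"), ctx=ctx)
        assert res.verdicts == {} and res.lp_count == 0

    def test_unknown_gene_reported_screen_continues(self, two_pathway_model, ctx):
        res = knockout_screen(two_pathway_model, ["mystery", "g1"],
                              rat("0.1"), ctx=ctx)
        assert res.errors == {"mystery": "unknown gene"}
        assert "g1" in res.verdicts

    def test_no_growth_baseline(self, analytic_model, ctx):
        res = knockout_screen(analytic_model, ["enz"], rat("1.9"), ctx=ctx)
        assert res.verdicts == {"enz": "no_growth_baseline"}
        assert res.lp_count == 0

    def test_bounds_restored_after_screen(self, two_pathway_model, ctx):
        before = (list(two_pathway_model.v_lower), list(two_pathway_model.v_upper))
        knockout_screen(two_pathway_model, ["g1"], rat("0.1"), ctx=ctx)
        assert (two_pathway_model.v_lower, two_pathway_model.v_upper) == before


class TestMagnitudeSummary:
    def test_basic_decade_accounting(self):
        s = flux_magnitude_summary({"a": 1e-14, "b": 1e-6, "c": 1e-4},
                                   {"a": "x", "b": "x", "c": "x"},
                                   feas_tol=1e-20)
        d = s.per_category["x"]
        assert d["min_exp"] == -14 and d["max_exp"] == -4
        assert d["median"] == pytest.approx(1e-6)

    def test_all_below_tolerance_is_empty(self):
        s = flux_magnitude_summary({"a": 1e-30}, {"a": "x"}, feas_tol=1e-20)
        assert s.per_category == {} and s.n_filtered == 0

    def test_fifteen_order_span(self):
        # the canonical extremes: 9.35e-14 (transcription) to 45.4 (exchange)
        s = flux_magnitude_summary({"lo": 9.35e-14, "hi": 45.4},
                                   {"lo": "transcription", "hi": "exchange"},
                                   feas_tol=1e-20)
        assert round(s.global_span_orders, 1) == 14.7

    def test_multiscale_optimum_spans_many_orders(self, multiscale_model,
                                                  multiscale_solution):
        cats = {rid: multiscale_model.annotation(rid).category
                for rid in multiscale_model.reaction_ids}
        v = dict(zip(multiscale_model.reaction_ids, multiscale_solution.v_star))
        s = flux_magnitude_summary(v, cats, feas_tol=1e-25)
        span_target = multiscale_model.metadata["magnitude_span_orders"]
        assert s.global_span_orders >= span_target - 2
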