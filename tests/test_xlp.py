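"""LP core: simplex correctness, scaling, warm starts, MPS, exact oracle."""
import math

import numpy as np
import pytest
from gmpy2 import mpq
from hypothesis import given, settings
from hypothesis import strategies as st

from quadme.arith import INF, ArithmeticContext, rat
from quadme.synthetic import random_rational_lp
from quadme.xlp import (LPError, LPProblem, read_mps, scale_problem, solve_lp,
                        vertex_oracle, write_mps)


def simple_lp():
    return LPProblem.from_dense([1], [[1]], ["le"], [3], [0], [10], sense="max")


class TestSolveBasics:
    def test_single_variable_maximum(self, ctx):
        sol = solve_lp(simple_lp(), ctx)
        assert sol.status == "optimal"
        assert float(sol.objective) == 3.0

    def test_infeasible_bounds_vs_row(self, ctx):
        lp = LPProblem.from_dense([1, 1], [[1, 1]], ["le"], [1],
                                  [2, 2], [10, 10], sense="max")
        sol = solve_lp(lp, ctx)
        assert sol.status == "infeasible"
        assert float(sol.phase1_infeasibility) > 0

    def test_unbounded(self, ctx):
        lp = LPProblem([1], "max", [{}], [], [], [0], [INF])
        assert solve_lp(lp, ctx).status == "unbounded"

    def test_degenerate_duplicate_rows(self, ctx):
        lp = LPProblem.from_dense([1, 1], [[1, 1], [1, 1]], ["le", "le"],
                                  [2, 2], [0, 0], [5, 5], sense="max")
        sol = solve_lp(lp, ctx)
        oracle = vertex_oracle(lp)
        assert sol.status == oracle.status == "optimal"
        assert abs(float(sol.objective) - float(oracle.objective)) < 1e-25

    def test_certification_residuals_on_every_solve(self, ctx):
        rng = np.random.default_rng(5)
        for _ in range(30):
            lp = random_rational_lp(rng)
            sol = solve_lp(lp, ctx)
            if sol.status == "optimal":
                rep = sol.residual_report
                assert float(rep["max_primal_residual"]) <= ctx.feas_tol
                assert float(rep["max_bound_violation"]) <= ctx.feas_tol
                assert float(rep["max_dual_infeasibility"]) <= ctx.opt_tol
                assert float(rep["max_complementarity"]) <= ctx.opt_tol


class TestOracle:
    def test_box_maximum(self):
        assert vertex_oracle(simple_lp()).objective == 3

    def test_unbounded_verdict(self):
        lp = LPProblem([1], "max", [{}], [], [], [0], [INF])
        assert vertex_oracle(lp).status == "unbounded"

    def test_size_cap(self):
        lp = LPProblem([1] * 9, "max", [{} for _ in range(9)], [], [],
                       [0] * 9, [1] * 9)
        with pytest.raises(LPError, match="cap"):
            vertex_oracle(lp)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_simplex_matches_exact_enumeration(self, seed):
        """Quad-precision simplex agrees with exact rational enumeration."""
        ctx = ArithmeticContext.quad()
        rng = np.random.default_rng(seed)
        lp = random_rational_lp(rng)
        oracle = vertex_oracle(lp)
        sol = solve_lp(lp, ctx)
        assert sol.status == oracle.status
        if oracle.status == "optimal":
            rel = abs(float(sol.objective) - float(oracle.objective))
            rel /= max(1.0, abs(float(oracle.objective)))
            assert rel <= 1e-20


class TestWarmStart:
    def test_bound_perturbation_same_objective(self, ctx):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 15:
            lp = random_rational_lp(rng)
            sol = solve_lp(lp, ctx)
            if sol.status != "optimal":
                continue
            pert = lp.copy()
            for j in range(pert.n_vars):
                if rng.random() < 0.5 and not math.isinf(float(pert.upper[j])):
                    pert.upper[j] = rat(pert.upper[j]) + mpq(1, 2)
            cold = solve_lp(pert, ctx)
            warm = solve_lp(pert, ctx, warm=sol.basis)
            assert warm.status == cold.status
            if cold.status == "optimal":
                rel = abs(float(warm.objective) - float(cold.objective))
                rel /= max(1.0, abs(float(cold.objective)))
                assert rel <= 1e-12
            checked += 1

    def test_incompatible_basis_is_repaired(self, ctx):
        lp = LPProblem.from_dense([1, 1], [[1, 2], [2, 1]], ["le", "le"],
                                  [4, 4], [0, 0], [5, 5], sense="max")
        donor = solve_lp(simple_lp(), ctx)
        sol = solve_lp(lp, ctx, warm=donor.basis)
        assert sol.status == "optimal"
        ref = solve_lp(lp, ctx)
        assert abs(float(sol.objective) - float(ref.objective)) < 1e-25


class TestScaling:
    def test_identity_matrix_unit_factors(self):
        lp = LPProblem.from_dense([1], [[1]], ["le"], [1], [0], [1])
        _slp, r, c = scale_problem(lp, "2")
        assert r == [1.0] and c == [1.0]

    def test_exact_unscale_round_trip(self):
        lp = LPProblem.from_dense(
            [mpq(1), mpq(3, 7)],
            [[rat("1e-8"), mpq(2)], [mpq(3), rat("1e8")]],
            ["le", "le"], [mpq(5), mpq(7)], [0, 0], [10, 10])
        slp, r, c = scale_problem(lp, "2")
        for j, col in enumerate(slp.cols):
            for i, a in col.items():
                back = rat(a) / (rat(str(r[i])) * rat(str(c[j])))
                assert back == rat(lp.cols[j][i])

    def test_dynamic_range_strictly_decreases(self):
        lp = LPProblem.from_dense([1, 1], [[rat("1e-8"), 0], [0, rat("1e8")]],
                                  ["le", "le"], [1, 1], [0, 0], [1, 1])
        slp, _r, _c = scale_problem(lp, "2")

        def dyn(p):
            vals = [abs(float(a)) for col in p.cols for a in col.values() if a != 0]
            return max(vals) / min(vals)

        assert dyn(slp) < dyn(lp)

    def test_scaling_neutral_objective(self, ctx):
        rng = np.random.default_rng(29)
        for _ in range(10):
            lp = random_rational_lp(rng)
            off = solve_lp(lp, ctx, scaling="off")
            on = solve_lp(lp, ctx, scaling="2")
            assert off.status == on.status
            if off.status == "optimal":
                rel = abs(float(off.objective) - float(on.objective))
                rel /= max(1.0, abs(float(off.objective)))
                assert rel <= 1e-12


class TestMps:
    def test_sections_present(self, tmp_path):
        path = tmp_path / "one.mps"
        write_mps(simple_lp(), path)
        text = path.read_text()
        for section in ("ROWS", "COLUMNS", "RHS", "BOUNDS", "ENDATA"):
            assert section in text

    def test_round_trip_dimensions_and_optimum(self, ctx, tmp_path):
        rng = np.random.default_rng(31)
        lp = random_rational_lp(rng)
        path = tmp_path / "r.mps"
        write_mps(lp, path)
        back = read_mps(path)
        assert back.n_vars == lp.n_vars and back.n_rows == lp.n_rows
        a = solve_lp(lp, ctx)
        b = solve_lp(back, ctx)
        assert a.status == b.status
        if a.status == "optimal":
            assert abs(float(a.objective) - float(b.objective)) < 1e-20

    def test_small_coefficient_full_precision(self, tmp_path):
        lp = LPProblem.from_dense([1], [[rat("9.35e-14")]], ["le"],
                                  [1], [0], [1])
        path = tmp_path / "c.mps"
        write_mps(lp, path)
        back = read_mps(path)
        assert rat(back.cols[0][0]) == rat("9.35e-14")


class TestDoublePrecisionMode:
    def test_native_context_solves(self, ctx_double):
        sol = solve_lp(simple_lp(), ctx_double)
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(3.0, abs=1e-9)


def test_iteration_limit_status():
    ctx = ArithmeticContext.quad(iteration_limit=1)
    lp = LPProblem.from_dense([1, 1], [[1, 2], [2, 1]], ["le", "le"],
                              [4, 4], [0, 0], [5, 5], sense="max")
    sol = solve_lp(lp, ctx)
    assert sol.status == "iteration_limit"
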