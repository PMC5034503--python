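"""High-precision growth maximization by sequential linearization.

The growth problem  max mu  s.t.  Sv = 0,  b_i'v - mu c_i'v {=,>=} 0,
bounds  is bilinear only through the products mu * (c_i'v).  Because the
feasible growth rates form an interval, any convergent local scheme
reaches the global optimum.  The solver here:

1. runs a coarse feasibility search (``bisect_me``) to a requested
   number of decimals (default 1), yielding mu0 strictly below mu* and a
   compatible simplex basis;
2. repeatedly linearizes the bilinear rows at the current point
   (mu_k, v_k) and maximizes mu over the linearized set inside a trust
   region on mu;
3. accepts a proposed mu only after a feasibility-restoration LP at that
   fixed growth rate succeeds -- the accepted iterate therefore
   satisfies every nonlinear row to the solver feasibility tolerance;
   rejected proposals halve the trust region;
4. stops when successive growth rates differ by at most ``mu_tol``
   (default 1e-15, the extended-precision regime where the growth rate
   carries ~15 reliable digits).

Starting the loop above mu* makes the restoration LP infeasible; the
solver then restarts from half the estimate (at most five times), the
documented remedy for a bad initial guess.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from gmpy2 import mpq

from .arith import INF, ArithmeticContext, isfin, rat
from .bisect_search import FeasibilityCheck, SearchError, bisect_me, feasible_at
from .model_core import MEModelSpec, fix_mu, mu_level_set_residual
from .xlp import Basis, LPProblem, solve_lp

MU_COLUMN = "mu"


class NLPError(RuntimeError):
    pass


@dataclass
class NLPResult:
    mu_star: object
    v_star: list
    major_iterations: int
    lp_evaluations: int
    residual_report: dict
    converged: bool
    history: list = field(default_factory=list)
    basis: Basis | None = None
    restarts: int = 0


def linearize_at(model: MEModelSpec, mu_k, v_k,
                 mu_bounds=(0, INF)) -> LPProblem:
    """First-order expansion of the bilinear rows about (mu_k, v_k).

    Each dilution row g_i(mu, v) = b_i'v - mu c_i'v becomes

        (b_i - mu_k c_i)' v - (c_i'v_k) (mu - mu_k)  {sense_i}  0,

    with mu an explicit bounded column (the trust region) and objective
    maximize mu.  The expansion is exact at the expansion point, so a
    feasible (mu_k, v_k) satisfies every linearized row with the original
    slack.  When the model names a growth reaction, the linear row
    v_growth - mu = 0 couples it to the mu column.
    """
    n = model.n_reactions
    if len(v_k) != n:
        raise ValueError("v_k length does not match reaction count")
    mu_k = rat(mu_k)
    if mu_k < 0:
        raise ValueError("mu_k must be nonnegative")
    m_met = model.n_metabolites
    n_dil = len(model.dilution_rows)
    cols = [dict() for _ in range(n + 1)]   # reactions then the mu column
    mu_col = cols[n]
    for (i, j), a in model.S.items():
        cols[j][i] = a
    row_senses = ["eq"] * m_met
    rhs = [mpq(0)] * m_met
    row_names = list(model.metabolite_ids)
    for k, row in enumerate(model.dilution_rows):
        ridx = m_met + k
        cv = mpq(0)
        for rid, coef in row.c.items():
            cv += rat(coef) * rat(v_k[model.rxn_index(rid)])
        for rid, coef in row.b.items():
            j = model.rxn_index(rid)
            cols[j][ridx] = cols[j].get(ridx, mpq(0)) + rat(coef)
        for rid, coef in row.c.items():
            j = model.rxn_index(rid)
            cols[j][ridx] = cols[j].get(ridx, mpq(0)) - mu_k * rat(coef)
        if cv != 0:
            mu_col[ridx] = -cv
        rhs.append(-cv * mu_k)
        row_senses.append(row.sense)
        row_names.append(row.label or f"dilution_{k}")
    m = m_met + n_dil
    if model.growth_reaction is not None:
        g = model.rxn_index(model.growth_reaction)
        cols[g][m] = cols[g].get(m, mpq(0)) + mpq(1)
        mu_col[m] = mu_col.get(m, mpq(0)) - mpq(1)
        rhs.append(mpq(0))
        row_senses.append("eq")
        row_names.append("growth_mu_link")
    objective = [mpq(0)] * n + [mpq(1)]
    lower = list(model.v_lower) + [max(mpq(0), rat(mu_bounds[0]))]
    upper = list(model.v_upper) + [mu_bounds[1] if not isfin(mu_bounds[1])
                                   else rat(mu_bounds[1])]
    return LPProblem(objective, "max", cols, row_senses, rhs, lower, upper,
                     col_names=list(model.reaction_ids) + [MU_COLUMN],
                     row_names=row_names)


def _nonlinear_violation(model, mu, v):
    """Worst violation of the true bilinear rows (negative part for ge)."""
    worst = 0
    for res, row in zip(mu_level_set_residual(model, mu, v),
                        model.dilution_rows):
        if row.sense == "eq":
            bad = abs(res)
        else:
            bad = -res if res < 0 else 0
        if bad > worst:
            worst = bad
    return worst


def solve_me(model: MEModelSpec, ctx: ArithmeticContext | None = None,
             decimals_coarse: int = 1, method_coarse: str = "golden",
             mu_tol: float = 1e-15, trust_region_init: float | None = None,
             max_major: int = 100, mu0=None,
             coarse_interval=(0, 2)) -> NLPResult:
    """Maximize growth to ~15 digits via coarse search + SLP refinement.

    ``mu0`` overrides the coarse search with an explicit starting growth
    rate (used to exercise the safeguard paths: mu0 = 0 converges, only
    more slowly; mu0 > mu* triggers restarts from mu0/2).
    """
    if ctx is None:
        ctx = ArithmeticContext.quad()
    lp_evals = 0
    restarts = 0
    history = []

    if mu0 is None:
        coarse = bisect_me(model, interval=coarse_interval,
                           method=method_coarse, ctx=ctx,
                           decimals=decimals_coarse)
        lp_evals += coarse.lp_evaluations
        mu_k = rat(coarse.mu_best)
        v_k = coarse.v_best
        basis = coarse.basis
        if v_k is None:
            chk = feasible_at(model, mu_k, ctx, warm=basis)
            lp_evals += 1
            v_k, basis = chk.solution.x, chk.basis
    else:
        mu_k = rat(mu0)
        if mu_k < 0:
            raise NLPError("mu0 must be nonnegative")
        basis = None
        while True:
            chk = feasible_at(model, mu_k, ctx, warm=basis)
            lp_evals += 1
            if chk.feasible:
                v_k, basis = chk.solution.x, chk.basis
                break
            restarts += 1
            if restarts > 5:
                raise NLPError(
                    "initial growth estimate infeasible after five restarts "
                    "(mu0 likely far above mu*)")
            basis = chk.basis
            mu_k = mu_k / 2

    mu_tol_r = rat(str(mu_tol))
    if trust_region_init is None:
        delta = rat(max(float(mu_k), 0.1)) / 2
    else:
        delta = rat(str(trust_region_init))
    history.append(mu_k)

    major = 0
    converged = False
    consec_full = 0
    final_chk: FeasibilityCheck | None = None
    while major < max_major:
        major += 1
        accepted = False
        inner = 0
        while not accepted:
            inner += 1
            if inner > 200:
                raise NLPError("trust-region loop failed to make progress")
            lo = mu_k - delta
            if lo < 0:
                lo = mpq(0)
            lp = linearize_at(model, mu_k, v_k, mu_bounds=(lo, mu_k + delta))
            sol = solve_lp(lp, ctx, warm=basis)
            lp_evals += 1
            if sol.status != "optimal":
                # at a feasible expansion point the linearized LP contains
                # (mu_k, v_k); failure indicates numerical trouble -- shrink
                delta = delta / 2
                if delta <= mu_tol_r / 4:
                    converged = True
                    accepted = True
                    break
                continue
            mu_c = mpq(sol.x[model.n_reactions])
            if mu_c < mu_k:
                mu_c = mu_k  # never step backwards: mu_k is known feasible
            chk = feasible_at(model, mu_c, ctx, warm=sol.basis)
            lp_evals += 1
            if chk.feasible:
                step = mu_c - mu_k
                hit_trust = mu_c >= mu_k + delta * mpq(99, 100)
                mu_k = mu_c
                # expand the next linearization about the linearized LP's own
                # point: it picks a dilution-efficient v, whereas the
                # restoration vertex (degenerate objective) may carry a
                # wasteful dilution load that throttles the next mu step
                v_k = sol.x[:model.n_reactions]
                basis = sol.basis
                final_chk = chk
                history.append(mu_k)
                accepted = True
                if hit_trust:
                    consec_full += 1
                    if consec_full >= 2:
                        delta = delta * 2
                        consec_full = 0
                else:
                    consec_full = 0
                if step <= mu_tol_r:
                    # probe forward before declaring optimality, so a
                    # stalled linearization cannot cause premature exit
                    probe = mu_k + max(100 * mu_tol_r, delta / 4)
                    pchk = feasible_at(model, probe, ctx, warm=basis)
                    lp_evals += 1
                    if pchk.feasible:
                        mu_k = probe
                        v_k = pchk.solution.x
                        basis = pchk.basis
                        final_chk = pchk
                        history.append(mu_k)
                    else:
                        converged = True
            else:
                delta = delta / 2
                consec_full = 0
                if delta <= mu_tol_r / 4:
                    # mu_k feasible, mu_k + delta infeasible: mu* is pinned
                    converged = True
                    accepted = True
        if converged:
            break

    if final_chk is None:
        chk = feasible_at(model, mu_k, ctx, warm=basis)
        lp_evals += 1
        final_chk = chk
        v_k, basis = chk.solution.x, chk.basis

    report = dict(final_chk.solution.residual_report)
    with ctx.activate():
        report["max_nonlinear_violation"] = _nonlinear_violation(
            model, ctx.num(mu_k), v_k)
    return NLPResult(mu_star=mu_k, v_star=v_k, major_iterations=major,
                     lp_evaluations=lp_evals, residual_report=report,
                     converged=converged, history=history, basis=basis,
                     restarts=restarts)


def certify_optimum(model: MEModelSpec, mu_star, delta=1e-9,
                    ctx: ArithmeticContext | None = None) -> bool:
    """True iff the model is feasible at mu*-delta and infeasible at mu*+delta."""
    if ctx is None:
        ctx = ArithmeticContext.quad()
    mu = rat(mu_star)
    d = rat(str(delta))
    below = mu - d
    if below < 0:
        below = mpq(0)
    lo = feasible_at(model, below, ctx)
    hi = feasible_at(model, mu + d, ctx, warm=lo.basis)
    return lo.feasible and not hi.feasible
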