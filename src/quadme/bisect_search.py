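"""Growth-rate maximization by feasibility search over fixed-mu LPs.

Because the dilution constraints are quasilinear in the growth rate, the
feasible growth rates form an interval [0, mu*]; mu* can therefore be
located by bisection on LP feasibility, or faster by golden-section
search.  Every LP after the first is warm-started from the previous
basis.

Binary search performs exactly ceil(log2((b-a)/epsilon)) interval
halvings, independent of the model.  The golden-section variant
maximizes the surrogate f(mu) = mu - K * infeasibility(mu) (K = 1e6),
which is unimodal with maximizer mu* for models of this class: f rises
with slope 1 on the feasible interval and falls steeply beyond it, where
the phase-1 infeasibility grows with mu.  The surrogate (rationale in
the package methods note) lets a pure feasibility sequence drive a
standard unimodal search.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from gmpy2 import mpq

from .arith import ArithmeticContext, rat
from .model_core import MEModelSpec, fix_mu
from .xlp import Basis, LPSolution, solve_lp

#: infeasibility penalty in the golden-section surrogate
GOLDEN_PENALTY = 1e6
#: inverse golden ratio: bracket reduction per new evaluation
INV_PHI = (math.sqrt(5.0) - 1.0) / 2.0


class SearchError(RuntimeError):
    pass


@dataclass
class FeasibilityCheck:
    feasible: bool
    infeasibility: object
    basis: Basis
    solution: LPSolution


@dataclass
class SearchResult:
    mu_lo: object
    mu_hi: object
    mu_best: object
    basis: Basis | None
    lp_evaluations: int
    iterations: int
    method: str
    v_best: list | None = None
    history: list = field(default_factory=list)


def feasible_at(model: MEModelSpec, mu, ctx: ArithmeticContext | None = None,
                warm: Basis | None = None) -> FeasibilityCheck:
    """Solve the fixed-mu LP and report feasibility plus the phase-1 gap.

    ``infeasibility`` is the phase-1 objective (total bound violation) at
    the phase-1 optimum: zero (up to feas_tol) exactly when the model is
    feasible at ``mu``.  The basis is returned for warm-start chaining.
    """
    if ctx is None:
        ctx = ArithmeticContext.quad()
    mu_r = rat(mu)
    if mu_r < 0:
        raise ValueError("mu must be nonnegative")
    sol = solve_lp(fix_mu(model, mu_r), ctx, warm=warm)
    feasible = sol.status == "optimal"
    infeas = 0 if feasible else sol.phase1_infeasibility
    return FeasibilityCheck(feasible, infeas, sol.basis, sol)


def _exact_halving_count(width: mpq, epsilon: mpq) -> int:
    """Smallest k with width / 2^k <= epsilon (exact rational arithmetic)."""
    k = 0
    w = width
    while w > epsilon:
        w = w / 2
        k += 1
        if k > 10_000:
            raise SearchError("bisection tolerance unreasonably small")
    return k


def bisect_me(model: MEModelSpec, interval=(0, 2), epsilon=1e-6,
              method="binary", ctx: ArithmeticContext | None = None,
              decimals: int | None = None) -> SearchResult:
    """Locate the maximal feasible growth rate within ``epsilon``.

    ``interval=(a, b)`` must have the model feasible at ``a`` (checked);
    if it is unexpectedly feasible at ``b`` the bracket is extended by
    doubling, at most four times.  ``decimals`` overrides ``epsilon`` as
    ``10**-decimals``.  Returns the largest growth rate proven feasible
    together with its basis; ``mu_lo``/``mu_hi`` bracket mu*.
    """
    if ctx is None:
        ctx = ArithmeticContext.quad()
    if decimals is not None:
        epsilon = mpq(10) ** -int(decimals)
    a, b = rat(interval[0]), rat(interval[1])
    eps = rat(epsilon)
    if not (a < b):
        raise SearchError("interval must satisfy a < b")
    if not (eps > 0):
        raise SearchError("epsilon must be positive")

    lp_evals = 0
    chk_a = feasible_at(model, a, ctx)
    lp_evals += 1
    if not chk_a.feasible:
        raise SearchError("model infeasible at lower bracket")
    chk_b = feasible_at(model, b, ctx, warm=chk_a.basis)
    lp_evals += 1
    extensions = 0
    while chk_b.feasible:
        if extensions >= 4:
            raise SearchError(
                "upper bracket still feasible after four doublings")
        width = b - a
        a, chk_a = b, chk_b
        b = a + 2 * width
        chk_b = feasible_at(model, b, ctx, warm=chk_b.basis)
        lp_evals += 1
        extensions += 1

    if method == "binary":
        k = _exact_halving_count(b - a, eps)
        lo, hi = a, b
        best = chk_a
        basis = chk_a.basis
        history = []
        for _ in range(k):
            mid = (lo + hi) / 2
            chk = feasible_at(model, mid, ctx, warm=basis)
            lp_evals += 1
            basis = chk.basis
            history.append((mid, chk.feasible))
            if chk.feasible:
                lo, best = mid, chk
            else:
                hi = mid
        return SearchResult(mu_lo=lo, mu_hi=hi, mu_best=lo, basis=best.basis,
                           lp_evaluations=lp_evals, iterations=k,
                           method="binary", v_best=best.solution.x,
                           history=history)

    if method != "golden":
        raise SearchError(f"unknown search method {method!r}")

    # golden-section maximization of mu - K * infeasibility(mu)
    def fval(chk: FeasibilityCheck, mu):
        pen = float(chk.infeasibility) if not chk.feasible else 0.0
        return float(mu) - GOLDEN_PENALTY * pen

    lo, hi = a, b
    best_mu, best_chk = a, chk_a
    basis = chk_a.basis
    iterations = 0
    history = []

    def probe(mu, basis):
        chk = feasible_at(model, mu, ctx, warm=basis)
        return chk

    import gmpy2

    def quantize(x):
        # keep probe points as dyadic rationals of bounded precision so the
        # exact fixed-mu coefficients stay cheap over many iterations
        return mpq(gmpy2.mpfr(x, 160))

    inv_phi = rat(str(INV_PHI))  # rational approximation of the ratio
    x1 = quantize(hi - inv_phi * (hi - lo))
    x2 = quantize(lo + inv_phi * (hi - lo))
    c1 = probe(x1, basis)
    lp_evals += 1
    basis = c1.basis
    c2 = probe(x2, basis)
    lp_evals += 1
    basis = c2.basis
    for chk, mu in ((c1, x1), (c2, x2)):
        if chk.feasible and mu > best_mu:
            best_mu, best_chk = mu, chk
    while hi - lo > eps:
        iterations += 1
        if fval(c1, x1) < fval(c2, x2):
            lo = x1
            x1, c1 = x2, c2
            x2 = quantize(lo + inv_phi * (hi - lo))
            c2 = probe(x2, basis)
            lp_evals += 1
            basis = c2.basis
            if c2.feasible and x2 > best_mu:
                best_mu, best_chk = x2, c2
            history.append((x2, c2.feasible))
        else:
            hi = x2
            x2, c2 = x1, c1
            x1 = quantize(hi - inv_phi * (hi - lo))
            c1 = probe(x1, basis)
            lp_evals += 1
            basis = c1.basis
            if c1.feasible and x1 > best_mu:
                best_mu, best_chk = x1, c1
            history.append((x1, c1.feasible))
    return SearchResult(mu_lo=min(lo, best_mu), mu_hi=hi, mu_best=best_mu,
                        basis=best_chk.basis, lp_evaluations=lp_evals,
                        iterations=iterations, method="golden",
                        v_best=best_chk.solution.x, history=history)
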