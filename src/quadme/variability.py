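"""Flux variability analysis, knockout screening and magnitude accounting.

All three tools operate on the fixed-growth LP reduction of an ME model.
FVA solves two LPs per reaction (min then max), chaining the simplex
basis from one LP to the next; warm-starting is the default and changes
nothing but the pivot count.  The knockout screen solves one feasibility
LP per gene at a single test growth rate: a gene is essential when
zeroing the bounds of its translation reactions makes that LP
infeasible.  The magnitude summary reports, per reaction category, the
spread of |flux| above the feasibility tolerance in integer decades.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from gmpy2 import mpq

from .arith import ArithmeticContext, isfin, rat
from .bisect_search import feasible_at
from .model_core import MEModelSpec, fix_mu
from .nlp_solve import NLPResult, solve_me
from .xlp import solve_lp


class VariabilityError(RuntimeError):
    pass


@dataclass
class FVAResult:
    ranges: dict            # reaction id -> (v_min, v_max)
    mu_used: object
    lp_count: int
    warm_start_hits: int
    statuses: dict          # reaction id -> (min status, max status)
    iterations_total: int = 0


@dataclass
class EssentialityResult:
    verdicts: dict          # gene -> essential | nonessential | no_growth_baseline
    mu_threshold: object
    lp_count: int
    errors: dict = field(default_factory=dict)
    iterations_total: int = 0


@dataclass
class MagnitudeSummary:
    per_category: dict      # category -> dict(min_exp, max_exp, median, mean, n)
    global_span_orders: float
    n_filtered: int


def vary_me(model: MEModelSpec, mu_fraction=1.0, reactions=None,
            ctx: ArithmeticContext | None = None, warm: bool = True,
            nlp_result: NLPResult | None = None) -> FVAResult:
    """Per-reaction flux ranges at a fixed fraction of the maximal growth.

    ``mu_fraction`` in (0, 1] scales mu* (computed by :func:`solve_me`
    unless an ``nlp_result`` is supplied).  The growth flux is fixed to
    the target value through the LP bounds.  With ``warm`` the first LP
    starts from the growth solver's basis and each subsequent LP from its
    predecessor's; cold mode solves every LP from scratch.
    """
    if ctx is None:
        ctx = ArithmeticContext.quad()
    frac = rat(str(mu_fraction)) if isinstance(mu_fraction, float) else rat(mu_fraction)
    if not (0 < frac <= 1):
        raise VariabilityError("mu_fraction must be in (0, 1]")
    if nlp_result is None:
        nlp_result = solve_me(model, ctx=ctx)
    mu_target = rat(nlp_result.mu_star) * frac
    if reactions is None:
        reactions = list(model.reaction_ids)
    # the growth optimum is certified only to feas_tol, so pinning mu at
    # exactly mu* can sit a hair beyond the true optimum; on a boundary
    # failure back the target off by a few tolerances and restart
    backoff = rat(str(ctx.feas_tol)) * 8 * max(mpq(1), mu_target)
    last_exc = None
    for attempt in range(3):
        mu = mu_target - attempt * backoff
        if mu < 0:
            mu = mpq(0)
        try:
            return _vary_at_fixed_mu(model, mu, reactions, ctx, warm,
                                     nlp_result)
        except _BoundaryInfeasible as exc:
            last_exc = exc
    raise VariabilityError(
        "model infeasible at the requested growth rate; "
        f"try a smaller mu_fraction ({last_exc})")


class _BoundaryInfeasible(Exception):
    pass


def _vary_at_fixed_mu(model, mu, reactions, ctx, warm, nlp_result):
    base = fix_mu(model, mu)
    chk = feasible_at(model, mu, ctx,
                      warm=nlp_result.basis if warm else None)
    lp_count = 0  # per the two-LPs-per-reaction accounting; the
    # feasibility presolve above only seeds the warm-start chain
    if not chk.feasible:
        raise _BoundaryInfeasible(
            f"infeasible at mu={float(mu)} "
            f"(violation {float(chk.infeasibility):.2e})")
    basis = chk.basis if warm else None
    ranges, statuses = {}, {}
    warm_hits = 0
    iters = 0
    for rid in reactions:
        j = model.rxn_index(rid)
        pair = []
        pair_status = []
        for sense in ("min", "max"):
            lp = base.copy()
            lp.objective = [mpq(0)] * lp.n_vars
            lp.objective[j] = mpq(1)
            lp.sense = sense
            sol = solve_lp(lp, ctx, warm=basis)
            lp_count += 1
            iters += sol.iterations
            if warm and basis is not None:
                warm_hits += 1
            if warm:
                basis = sol.basis
            if sol.status == "optimal":
                pair.append(sol.objective)
                pair_status.append("optimal")
            elif sol.status == "unbounded":
                pair.append(-math.inf if sense == "min" else math.inf)
                pair_status.append("unbounded")
            elif sol.status == "infeasible":
                raise _BoundaryInfeasible(
                    f"subproblem for {rid!r} infeasible at mu={float(mu)}")
            else:
                raise VariabilityError(
                    f"FVA subproblem for {rid!r} returned {sol.status}")
        ranges[rid] = (pair[0], pair[1])
        statuses[rid] = tuple(pair_status)
    return FVAResult(ranges=ranges, mu_used=mu, lp_count=lp_count,
                     warm_start_hits=warm_hits, statuses=statuses,
                     iterations_total=iters)


def gene_map(model: MEModelSpec) -> dict:
    """gene -> list of translation reaction ids, from the annotations."""
    out = {}
    for rid in model.reaction_ids:
        ann = model.annotation(rid)
        if ann.category == "translation" and ann.gene:
            out.setdefault(ann.gene, []).append(rid)
    return out


def knockout_screen(model: MEModelSpec, genes, mu_test,
                    ctx: ArithmeticContext | None = None,
                    warm: bool = True) -> EssentialityResult:
    """Single-gene essentiality at a fixed test growth rate.

    Per gene: zero both bounds of its translation reactions, solve one
    feasibility LP at ``mu_test``, restore the bounds.  A gene is
    essential when that LP is infeasible.  Unknown genes produce error
    entries; the screen continues.
    """
    if ctx is None:
        ctx = ArithmeticContext.quad()
    mu = rat(mu_test)
    gmap = gene_map(model)
    base = feasible_at(model, mu, ctx)
    if not base.feasible:
        return EssentialityResult(
            verdicts={g: "no_growth_baseline" for g in genes},
            mu_threshold=mu, lp_count=0)
    work = model.copy()
    verdicts, errors = {}, {}
    basis = base.basis if warm else None
    lp_count = 0
    iters = 0
    for gene in genes:
        if gene not in gmap:
            errors[gene] = "unknown gene"
            continue
        saved = []
        for rid in gmap[gene]:
            j = work.rxn_index(rid)
            saved.append((j, work.v_lower[j], work.v_upper[j]))
            work.v_lower[j] = mpq(0)
            work.v_upper[j] = mpq(0)
        chk = feasible_at(work, mu, ctx, warm=basis)
        lp_count += 1
        iters += chk.solution.iterations
        if warm:
            basis = chk.basis
        verdicts[gene] = "nonessential" if chk.feasible else "essential"
        for j, lo, hi in saved:
            work.v_lower[j] = lo
            work.v_upper[j] = hi
    return EssentialityResult(verdicts=verdicts, mu_threshold=mu,
                              lp_count=lp_count, errors=errors,
                              iterations_total=iters)


def flux_magnitude_summary(v, categories,
                           feas_tol: float = 1e-15) -> MagnitudeSummary:
    """Category-wise decade spread of |flux| above the feasibility floor.

    ``v`` maps reaction id -> flux (or is paired positionally when given
    with a list of (id, category)).  Only fluxes with |v| > feas_tol
    enter; exponents are floor(log10 |v|) of the smallest and largest
    surviving flux, matching the integer-decade reporting convention.
    The global span is log10(max/min) over all surviving fluxes.
    """
    if not isinstance(v, dict):
        raise TypeError("v must map reaction id -> flux")
    per_cat_vals = {}
    all_vals = []
    for rid, flux in v.items():
        cat = categories.get(rid, "uncategorized")
        a = abs(float(flux))
        if a <= feas_tol:
            continue
        per_cat_vals.setdefault(cat, []).append(a)
        all_vals.append(a)
    per_category = {}
    for cat, vals in sorted(per_cat_vals.items()):
        vals.sort()
        n = len(vals)
        median = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
        per_category[cat] = {
            "min_exp": math.floor(math.log10(vals[0])),
            "max_exp": math.floor(math.log10(vals[-1])),
            "median": median,
            "mean": sum(vals) / n,
            "n": n,
        }
    span = math.log10(max(all_vals) / min(all_vals)) if all_vals else 0.0
    return MagnitudeSummary(per_category=per_category,
                            global_span_orders=span,
                            n_filtered=len(all_vals))
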