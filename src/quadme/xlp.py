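"""Extended-precision bounded-variable revised simplex.

This is the numerical core of the package: a deterministic two-phase
revised simplex over software extended-precision floats (or native
doubles), with

* iterative geometric-mean scaling by exactly invertible powers of two,
* warm starts from a previous basis (repaired, never rejected),
* residual certification of every optimal solution, and
* an exact rational vertex-enumeration oracle for cross-checking on
  small instances.

Design choices: Dantzig pricing with a switch to Bland's rule after 50
consecutive degenerate pivots; ratio-test ties broken by lowest variable
index; dense basis inverse refreshed periodically by Gauss-Jordan
elimination.  All choices favour determinism over speed; the intended
problem scale is a few thousand columns at most.
"""
from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass, field
from fractions import Fraction

import gmpy2
from gmpy2 import mpq

from .arith import INF, ArithmeticContext, isfin, rat, rat_to_str

logger = logging.getLogger(__name__)

BASIC, AT_LOWER, AT_UPPER, FREE = "B", "L", "U", "F"

#: number of pivots between dense refactorizations of the basis inverse
REFACTOR_INTERVAL = 60
#: consecutive degenerate pivots before switching to Bland's rule
BLAND_TRIGGER = 50


class LPError(Exception):
    pass


class LPProblem:
    """A bounded-variable LP: optimize c'x s.t. row constraints and bounds.

    Columns are stored sparsely as ``{row_index: coefficient}`` dicts;
    coefficients may be exact rationals, ints or floats.  Row senses are
    ``"eq"``, ``"ge"`` or ``"le"``; right-hand sides must be finite.
    """

    def __init__(self, objective, sense, cols, row_senses, rhs,
                 lower, upper, col_names=None, row_names=None):
        n = len(cols)
        m = len(rhs)
        if not (len(objective) == len(lower) == len(upper) == n):
            raise LPError("inconsistent column dimensions")
        if len(row_senses) != m:
            raise LPError("inconsistent row dimensions")
        if sense not in ("max", "min"):
            raise LPError(f"unknown objective sense {sense!r}")
        for s in row_senses:
            if s not in ("eq", "ge", "le"):
                raise LPError(f"unknown row sense {s!r}")
        for b in rhs:
            if not isfin(b):
                raise LPError("right-hand sides must be finite")
        for col in cols:
            for i in col:
                if not (0 <= i < m):
                    raise LPError("column entry references unknown row")
        self.objective = list(objective)
        self.sense = sense
        self.cols = [dict(col) for col in cols]
        self.row_senses = list(row_senses)
        self.rhs = list(rhs)
        self.lower = list(lower)
        self.upper = list(upper)
        self.col_names = list(col_names) if col_names else [f"x{j}" for j in range(n)]
        self.row_names = list(row_names) if row_names else [f"r{i}" for i in range(m)]
        if len(self.col_names) != n or len(self.row_names) != m:
            raise LPError("name arrays have wrong length")

    @property
    def n_vars(self):
        return len(self.cols)

    @property
    def n_rows(self):
        return len(self.rhs)

    @classmethod
    def from_dense(cls, c, A, row_senses, rhs, lower, upper, sense="max",
                   col_names=None, row_names=None):
        n = len(c)
        cols = [{} for _ in range(n)]
        for i, row in enumerate(A):
            if len(row) != n:
                raise LPError("dense matrix row has wrong length")
            for j, a in enumerate(row):
                if a != 0:
                    cols[j][i] = a
        return cls(c, sense, cols, row_senses, rhs, lower, upper,
                   col_names, row_names)

    def copy(self):
        return LPProblem(self.objective, self.sense, self.cols,
                         self.row_senses, self.rhs, self.lower, self.upper,
                         self.col_names, self.row_names)


@dataclass
class Basis:
    """Simplex basis: per-variable status plus the ordered basic set.

    Statuses cover structural variables followed by one slack per row;
    ``basic`` holds column indices into that combined ordering, one per
    row position.
    """

    statuses: list
    basic: list
    n_structural: int | None = None

    def copy(self):
        return Basis(list(self.statuses), list(self.basic), self.n_structural)


@dataclass
class LPSolution:
    status: str                      # optimal | infeasible | unbounded | iteration_limit
    x: list | None
    duals: list | None
    reduced_costs: list | None
    objective: object
    basis: Basis | None
    residual_report: dict
    iterations: int
    phase1_infeasibility: object = 0


# ----------------------------------------------------------------------
# scaling


def _pow2_round(f: float) -> float:
    if f <= 0 or not math.isfinite(f):
        return 1.0
    return 2.0 ** round(math.log2(f))


def scale_problem(lp: LPProblem, mode="2", max_passes=10):
    """Geometric-mean scaling with exactly invertible power-of-two factors.

    Mode ``"2"``: alternate row and column geometric-mean passes (up to
    ``max_passes`` or until the factors change by less than 10 %), then a
    final column pass that normalizes the largest scaled entry of each
    column to 1.  Mode ``"off"`` returns identity factors.  Factors are
    rounded to powers of two so that scaling and unscaling reproduce every
    coefficient exactly.
    """
    m, n = lp.n_rows, lp.n_vars
    r = [1.0] * m
    s = [1.0] * n
    if str(mode) in ("off", "0") or m == 0 or n == 0:
        return lp.copy(), r, s
    if str(mode) != "2":
        raise LPError(f"unknown scaling mode {mode!r}")

    entries = []  # (i, j, |a| as float)
    for j, col in enumerate(lp.cols):
        for i, a in col.items():
            fa = abs(float(a))
            if fa > 0:
                entries.append((i, j, fa))
    if not entries:
        return lp.copy(), r, s

    by_row = [[] for _ in range(m)]
    by_col = [[] for _ in range(n)]
    for i, j, fa in entries:
        by_row[i].append((j, fa))
        by_col[j].append((i, fa))

    for _ in range(max_passes):
        change = 1.0
        for i in range(m):
            if not by_row[i]:
                continue
            vals = [fa * r[i] * s[j] for j, fa in by_row[i]]
            f = 1.0 / math.sqrt(min(vals) * max(vals))
            change = max(change, f, 1.0 / f if f > 0 else 1.0)
            r[i] *= f
        for j in range(n):
            if not by_col[j]:
                continue
            vals = [fa * r[i] * s[j] for i, fa in by_col[j]]
            f = 1.0 / math.sqrt(min(vals) * max(vals))
            change = max(change, f, 1.0 / f if f > 0 else 1.0)
            s[j] *= f
        if change < 1.1:
            break
    r = [_pow2_round(v) for v in r]
    s = [_pow2_round(v) for v in s]
    # final column pass: largest |entry| per column -> 1
    for j in range(n):
        if not by_col[j]:
            continue
        biggest = max(fa * r[i] * s[j] for i, fa in by_col[j])
        s[j] *= _pow2_round(1.0 / biggest)

    def mulq(a, f):
        if f == 1.0:
            return a
        q = Fraction(f)
        if isinstance(a, float):
            return a * f
        return rat(a) * mpq(q.numerator, q.denominator)

    cols = []
    for j, col in enumerate(lp.cols):
        cols.append({i: mulq(a, r[i] * s[j]) for i, a in col.items()})
    rhs = [mulq(b, r[i]) for i, b in enumerate(lp.rhs)]
    obj = [mulq(c, s[j]) for j, c in enumerate(lp.objective)]
    lo = [lp.lower[j] if not isfin(lp.lower[j]) else mulq(lp.lower[j], 1.0 / s[j])
          for j in range(n)]
    hi = [lp.upper[j] if not isfin(lp.upper[j]) else mulq(lp.upper[j], 1.0 / s[j])
          for j in range(n)]
    scaled = LPProblem(obj, lp.sense, cols, lp.row_senses, rhs, lo, hi,
                       lp.col_names, lp.row_names)
    return scaled, r, s


# ----------------------------------------------------------------------
# the simplex engine


class _Simplex:
    def __init__(self, lp: LPProblem, ctx: ArithmeticContext, warm: Basis | None,
                 log_interval: int | None = None):
        self.ctx = ctx
        self.lp = lp
        self.log_interval = log_interval
        num = ctx.num
        n, m = lp.n_vars, lp.n_rows
        self.n, self.m = n, m
        self.N = n + m
        zero = ctx.zero
        # columns: structural then one slack per row
        self.cols = []
        for col in lp.cols:
            self.cols.append([(i, num(a)) for i, a in col.items() if a != 0])
        one = ctx.one
        for i in range(m):
            self.cols.append([(i, one)])
        # internal minimization costs
        sign = -1 if lp.sense == "max" else 1
        self.cost = [num(c) * sign for c in lp.objective] + [zero] * m
        # bounds
        self.lo = [num(b) if isfin(b) else -INF for b in lp.lower]
        self.hi = [num(b) if isfin(b) else INF for b in lp.upper]
        for sense in lp.row_senses:
            if sense == "eq":
                self.lo.append(zero)
                self.hi.append(zero)
            elif sense == "le":
                self.lo.append(zero)
                self.hi.append(INF)
            else:  # ge
                self.lo.append(-INF)
                self.hi.append(zero)
        self.b = [num(v) for v in lp.rhs]
        self.ftol = num(ctx.feas_tol)
        self.dtol = num(ctx.opt_tol)
        self.ztol = num(ctx.pivot_tol())
        self.iterations = 0
        self.pivots_since_factor = 0
        self.degenerate_run = 0
        self._init_basis(warm)

    # -- basis handling ------------------------------------------------

    def _default_status(self, j):
        if isfin(self.lo[j]):
            return AT_LOWER
        if isfin(self.hi[j]):
            return AT_UPPER
        return FREE

    def _init_basis(self, warm: Basis | None):
        n, m, N = self.n, self.m, self.N
        statuses = [self._default_status(j) for j in range(N)]
        if warm is not None:
            ws = warm.statuses
            wN = len(ws)
            # structural statuses map positionally; slacks map by row
            if warm.n_structural is not None:
                wn = warm.n_structural
            else:
                wn = wN - m if wN >= m else wN
            for j in range(min(n, wn)):
                statuses[j] = ws[j]
            for i in range(m):
                k = wn + i
                if 0 <= k < wN:
                    statuses[n + i] = ws[k]
            basic = [j for j in range(N) if statuses[j] == BASIC]
            if len(basic) > m:
                for j in reversed(basic[m:]):
                    statuses[j] = self._default_status(j)
                basic = basic[:m]
            if len(basic) < m:
                for i in range(m):
                    if len(basic) == m:
                        break
                    if statuses[n + i] != BASIC:
                        statuses[n + i] = BASIC
                        basic.append(n + i)
        else:
            for i in range(m):
                statuses[n + i] = BASIC
            basic = [n + i for i in range(m)]
        # nonbasic statuses must be representable
        for j in range(N):
            if statuses[j] == BASIC:
                continue
            if statuses[j] == AT_LOWER and not isfin(self.lo[j]):
                statuses[j] = self._default_status(j)
            elif statuses[j] == AT_UPPER and not isfin(self.hi[j]):
                statuses[j] = self._default_status(j)
        self.statuses = statuses
        self.basic = basic
        self._repair_and_factor()

    def _repair_and_factor(self):
        """LU-check the basic set; replace dependent columns with slacks."""
        m = self.m
        for _attempt in range(m + 1):
            bad = self._invert()
            if bad is None:
                return
            pos, uncovered_rows = bad
            old = self.basic[pos]
            self.statuses[old] = self._default_status(old)
            row = uncovered_rows[0]
            repl = self.n + row
            if self.statuses[repl] == BASIC:
                # its slack already basic elsewhere; pick any uncovered slack
                repl = None
                for rr in uncovered_rows:
                    if self.statuses[self.n + rr] != BASIC:
                        repl = self.n + rr
                        break
                if repl is None:
                    raise LPError("basis repair failed: no replacement slack")
            self.statuses[repl] = BASIC
            self.basic[pos] = repl
        raise LPError("basis repair failed: singular after repeated attempts")

    def _invert(self):
        """Gauss-Jordan inverse of the basis matrix.

        Returns None on success (setting ``self.Binv``); on singularity
        returns ``(position, uncovered_rows)`` identifying a dependent
        basic column and rows without a pivot.
        """
        m = self.m
        zero = self.ctx.zero
        one = self.ctx.one
        # build dense basis matrix: columns in basic order
        B = [[zero] * m for _ in range(m)]
        for p, j in enumerate(self.basic):
            for i, a in self.cols[j]:
                B[i][p] = a
        Inv = [[zero] * m for _ in range(m)]
        for i in range(m):
            Inv[i][i] = one
        rowperm = list(range(m))
        used = [False] * m
        for k in range(m):  # eliminate column k (basic position k)
            piv_row, piv_val = -1, zero
            for i in range(m):
                if used[i]:
                    continue
                v = abs(B[i][k])
                if v > piv_val:
                    piv_val, piv_row = v, i
            if piv_row < 0 or piv_val <= self.ztol:
                uncovered = [i for i in range(m) if not used[i]]
                return k, uncovered
            used[piv_row] = True
            rowperm[k] = piv_row
            pv = B[piv_row][k]
            inv_pv = one / pv
            Brow = B[piv_row]
            Irow = Inv[piv_row]
            for c in range(m):
                Brow[c] *= inv_pv
                Irow[c] *= inv_pv
            for i in range(m):
                if i == piv_row:
                    continue
                f = B[i][k]
                if f == 0:
                    continue
                Bi, Ii = B[i], Inv[i]
                for c in range(m):
                    Bi[c] -= f * Brow[c]
                    Ii[c] -= f * Irow[c]
        # now rows are a permuted identity: B[rowperm[k]][k] == 1
        Binv = [None] * m
        for k in range(m):
            Binv[k] = Inv[rowperm[k]]
        self.Binv = Binv
        self.pivots_since_factor = 0
        return None

    # -- iteration pieces ---------------------------------------------

    def _nonbasic_value(self, j):
        st = self.statuses[j]
        if st == AT_LOWER:
            return self.lo[j]
        if st == AT_UPPER:
            return self.hi[j]
        return self.ctx.zero

    def _compute_xB(self):
        m = self.m
        t = list(self.b)
        for j in range(self.N):
            if self.statuses[j] == BASIC:
                continue
            v = self._nonbasic_value(j)
            if v == 0:
                continue
            for i, a in self.cols[j]:
                t[i] -= a * v
        Binv = self.Binv
        xB = []
        for p in range(m):
            row = Binv[p]
            acc = self.ctx.zero
            for i in range(m):
                ti = t[i]
                if ti != 0:
                    acc += row[i] * ti
            xB.append(acc)
        return xB

    def _infeasibility(self, xB):
        total = self.ctx.zero
        worst = self.ctx.zero
        for p, j in enumerate(self.basic):
            v = xB[p]
            lo, hi = self.lo[j], self.hi[j]
            if isfin(lo) and v < lo:
                d = lo - v
            elif isfin(hi) and v > hi:
                d = v - hi
            else:
                continue
            total += d
            if d > worst:
                worst = d
        return total, worst

    def _duals(self, cb):
        m = self.m
        Binv = self.Binv
        y = [self.ctx.zero] * m
        for p in range(m):
            c = cb[p]
            if c == 0:
                continue
            row = Binv[p]
            for i in range(m):
                ri = row[i]
                if ri != 0:
                    y[i] += c * ri
        return y

    def _ftran(self, j):
        m = self.m
        col = self.cols[j]
        Binv = self.Binv
        w = []
        for p in range(m):
            row = Binv[p]
            acc = self.ctx.zero
            for i, a in col:
                acc += row[i] * a
            w.append(acc)
        return w

    def _pivot_update(self, pos, w):
        """Replace basic position ``pos``; update the dense inverse."""
        m = self.m
        piv = w[pos]
        Binv = self.Binv
        prow = Binv[pos]
        inv_p = self.ctx.one / piv
        for i in range(m):
            prow[i] *= inv_p
        for p in range(m):
            if p == pos:
                continue
            f = w[p]
            if f == 0:
                continue
            row = Binv[p]
            for i in range(m):
                row[i] -= f * prow[i]
        self.pivots_since_factor += 1

    # -- main loop ------------------------------------------------------

    def run(self):
        ctx = self.ctx
        N, m = self.N, self.m
        # fast path: inconsistent bounds
        gap_bad = None
        for j in range(N):
            if isfin(self.lo[j]) and isfin(self.hi[j]) and self.lo[j] > self.hi[j] + self.ftol:
                g = self.lo[j] - self.hi[j]
                if gap_bad is None or g > gap_bad:
                    gap_bad = g
        if gap_bad is not None:
            return self._finish("infeasible", None, phase1_inf=gap_bad)

        bland = False
        while True:
            if self.iterations > ctx.iteration_limit:
                xB = self._compute_xB()
                return self._finish("iteration_limit", xB)
            if self.pivots_since_factor >= REFACTOR_INTERVAL:
                self._repair_and_factor()
            xB = self._compute_xB()
            total_inf, worst_inf = self._infeasibility(xB)
            phase1 = worst_inf > self.ftol
            if self.log_interval and self.iterations % self.log_interval == 0:
                obj = sum(self.cost[j] * xB[p]
                          for p, j in enumerate(self.basic) if self.cost[j] != 0)
                logger.info("phase=%d iter=%d objective=%.12g infeasibility=%.3e",
                            1 if phase1 else 2, self.iterations,
                            float(obj), float(total_inf))
            # cost of basic variables
            cb = []
            if phase1:
                for p, j in enumerate(self.basic):
                    v = xB[p]
                    if isfin(self.lo[j]) and v < self.lo[j] - self.ftol:
                        cb.append(-ctx.one)
                    elif isfin(self.hi[j]) and v > self.hi[j] + self.ftol:
                        cb.append(ctx.one)
                    else:
                        cb.append(ctx.zero)
            else:
                cb = [self.cost[j] for j in self.basic]
            y = self._duals(cb)
            # pricing
            best_j, best_score, best_dir, best_d = -1, ctx.zero, 0, ctx.zero
            for j in range(N):
                st = self.statuses[j]
                if st == BASIC:
                    continue
                cj = ctx.zero if phase1 else self.cost[j]
                d = cj
                for i, a in self.cols[j]:
                    yi = y[i]
                    if yi != 0:
                        d -= yi * a
                if st == AT_LOWER:
                    if d < -self.dtol:
                        score, direction = -d, 1
                    else:
                        continue
                elif st == AT_UPPER:
                    if d > self.dtol:
                        score, direction = d, -1
                    else:
                        continue
                else:  # FREE
                    if d < -self.dtol:
                        score, direction = -d, 1
                    elif d > self.dtol:
                        score, direction = d, -1
                    else:
                        continue
                if bland:
                    best_j, best_dir, best_d = j, direction, d
                    break
                if score > best_score:
                    best_j, best_score, best_dir, best_d = j, score, direction, d
            if best_j < 0:
                if phase1:
                    return self._finish("infeasible", xB, phase1_inf=total_inf)
                return self._finish("optimal", xB)

            q, s = best_j, best_dir
            w = self._ftran(q)
            # ratio test
            t_best = INF
            leave_pos = -1
            leave_to = None  # status the leaving variable takes
            for p, j in enumerate(self.basic):
                wp = w[p]
                if abs(wp) <= self.ztol:
                    continue
                rrate = -s * wp  # dx_basic/dt
                v = xB[p]
                lo, hi = self.lo[j], self.hi[j]
                target = None
                if phase1:
                    if rrate > 0:
                        if isfin(lo) and v < lo - self.ftol:
                            target, st_to = lo, AT_LOWER
                        elif isfin(hi):
                            target, st_to = hi, AT_UPPER
                    else:
                        if isfin(hi) and v > hi + self.ftol:
                            target, st_to = hi, AT_UPPER
                        elif isfin(lo):
                            target, st_to = lo, AT_LOWER
                else:
                    if rrate > 0:
                        if isfin(hi):
                            target, st_to = hi, AT_UPPER
                    else:
                        if isfin(lo):
                            target, st_to = lo, AT_LOWER
                if target is None:
                    continue
                tr = (target - v) / rrate
                if tr < 0:
                    tr = ctx.zero
                if tr < t_best or (tr == t_best and (leave_pos < 0 or j < self.basic[leave_pos])):
                    t_best = tr
                    leave_pos = p
                    leave_to = st_to
            # entering variable's own opposite bound (bound flip)
            t_flip = INF
            if isfin(self.lo[q]) and isfin(self.hi[q]):
                t_flip = self.hi[q] - self.lo[q]
            if leave_pos < 0 and not isfin(t_flip):
                if phase1:
                    raise LPError("phase-1 direction unblocked: numerical breakdown")
                return self._finish("unbounded", xB)
            self.iterations += 1
            if t_flip <= t_best:
                # bound flip, no basis change
                self.statuses[q] = AT_UPPER if self.statuses[q] == AT_LOWER else AT_LOWER
                step = t_flip
            else:
                step = t_best
                jl = self.basic[leave_pos]
                self.statuses[jl] = leave_to
                self.statuses[q] = BASIC
                self.basic[leave_pos] = q
                self._pivot_update(leave_pos, w)
            if step <= self.ftol:
                self.degenerate_run += 1
                if self.degenerate_run >= BLAND_TRIGGER:
                    bland = True
            else:
                self.degenerate_run = 0
                bland = False

    # -- wrap up ---------------------------------------------------------

    def _finish(self, status, xB, phase1_inf=0):
        ctx = self.ctx
        n, m, N = self.n, self.m, self.N
        val = [None] * N
        for j in range(N):
            if self.statuses[j] != BASIC:
                val[j] = self._nonbasic_value(j)
        if xB is not None:
            for p, j in enumerate(self.basic):
                val[j] = xB[p]
        else:
            for p, j in enumerate(self.basic):
                val[j] = ctx.zero
        # duals and reduced costs w.r.t. the true cost
        cb = [self.cost[j] for j in self.basic]
        y = self._duals(cb)
        rc = []
        for j in range(N):
            d = self.cost[j]
            for i, a in self.cols[j]:
                d -= y[i] * a
            rc.append(d)
        sign = -1 if self.lp.sense == "max" else 1
        x = val[:n]
        duals = [-yi for yi in y] if sign == -1 else list(y)
        red = [sign * rc[j] for j in range(n)]
        obj = None
        if status == "optimal":
            obj = ctx.zero
            for j in range(n):
                c = self.lp.objective[j]
                if c != 0:
                    obj += ctx.num(c) * x[j]
        basis = Basis(list(self.statuses), list(self.basic), n)
        return LPSolution(status=status, x=x, duals=duals, reduced_costs=red,
                          objective=obj, basis=basis, residual_report={},
                          iterations=self.iterations,
                          phase1_infeasibility=phase1_inf)


def _residual_report(lp: LPProblem, ctx: ArithmeticContext, sol: LPSolution):
    """Certify a solution against the *original* problem data."""
    num = ctx.num
    zero = ctx.zero
    x = sol.x
    if x is None:
        return {"max_primal_residual": INF, "max_bound_violation": INF,
                "max_dual_infeasibility": INF, "max_complementarity": INF}
    m, n = lp.n_rows, lp.n_vars
    ax = [zero] * m
    for j, col in enumerate(lp.cols):
        xj = x[j]
        if xj == 0:
            continue
        for i, a in col.items():
            ax[i] += num(a) * xj
    max_row = zero
    for i in range(m):
        r = ax[i] - num(lp.rhs[i])
        sense = lp.row_senses[i]
        if sense == "eq":
            v = abs(r)
        elif sense == "ge":
            v = -r if r < 0 else zero
        else:
            v = r if r > 0 else zero
        if v > max_row:
            max_row = v
    max_bnd = zero
    for j in range(n):
        lo, hi = lp.lower[j], lp.upper[j]
        if isfin(lo):
            v = num(lo) - x[j]
            if v > max_bnd:
                max_bnd = v
        if isfin(hi):
            v = x[j] - num(hi)
            if v > max_bnd:
                max_bnd = v
    max_dual = zero
    max_comp = zero
    if sol.reduced_costs is not None and sol.status == "optimal":
        sign = -1 if lp.sense == "max" else 1
        for j in range(n):
            d = sign * sol.reduced_costs[j]  # minimization convention
            st = sol.basis.statuses[j]
            if st == BASIC:
                if abs(d) > max_comp:
                    max_comp = abs(d)
                continue
            if st == AT_LOWER:
                v = -d if d < 0 else zero
            elif st == AT_UPPER:
                v = d if d > 0 else zero
            else:
                v = abs(d)
            if v > max_dual:
                max_dual = v
            # complementarity: nonbasic variables must sit on their bound
            dist = INF
            if isfin(lp.lower[j]):
                dist = min(dist, abs(x[j] - num(lp.lower[j])))
            if isfin(lp.upper[j]):
                dist = min(dist, abs(x[j] - num(lp.upper[j])))
            if isfin(dist):
                v = abs(d) * dist
                if v > max_comp:
                    max_comp = v
    return {"max_primal_residual": max_row,
            "max_bound_violation": max_bnd,
            "max_dual_infeasibility": max_dual,
            "max_complementarity": max_comp}


def solve_lp(lp: LPProblem, ctx: ArithmeticContext | None = None,
             warm: Basis | None = None, scaling="off",
             log_interval: int | None = None) -> LPSolution:
    """Solve a bounded-variable LP with the two-phase revised simplex.

    ``warm`` may come from a different but structurally related problem;
    it is repaired (statuses retained, rank-deficient basic sets completed
    by slacks in row order) rather than rejected.  ``scaling`` is ``"off"``
    or ``"2"`` (alternating geometric-mean scaling).  The returned
    solution carries a residual report computed against the *unscaled*
    problem data.
    """
    if ctx is None:
        ctx = ArithmeticContext.quad()
    with ctx.activate():
        if str(scaling) == "2":
            slp, rfac, cfac = scale_problem(lp, "2")
        else:
            slp, rfac, cfac = lp, None, None
        engine = _Simplex(slp, ctx, warm, log_interval=log_interval)
        sol = engine.run()
        if rfac is not None and sol.x is not None:
            sol.x = [sol.x[j] * ctx.num(cfac[j]) for j in range(lp.n_vars)]
            sol.duals = [sol.duals[i] * ctx.num(rfac[i]) for i in range(lp.n_rows)]
            sol.reduced_costs = [sol.reduced_costs[j] / ctx.num(cfac[j])
                                 for j in range(lp.n_vars)]
            if sol.status == "optimal":
                obj = ctx.zero
                for j in range(lp.n_vars):
                    c = lp.objective[j]
                    if c != 0:
                        obj += ctx.num(c) * sol.x[j]
                sol.objective = obj
        sol.residual_report = _residual_report(lp, ctx, sol)
        return sol


# ----------------------------------------------------------------------
# exact rational vertex-enumeration oracle


@dataclass
class OracleResult:
    status: str          # optimal | infeasible | unbounded
    objective: object    # mpq or None
    x: list | None = None


_ORACLE_BOX = mpq(2) ** 40


def _solve_exact(Arows, brhs):
    """Solve a square rational system by Gaussian elimination; None if singular."""
    n = len(brhs)
    M = [list(row) + [brhs[i]] for i, row in enumerate(Arows)]
    for k in range(n):
        piv = -1
        for i in range(k, n):
            if M[i][k] != 0:
                piv = i
                break
        if piv < 0:
            return None
        M[k], M[piv] = M[piv], M[k]
        pk = M[k][k]
        for i in range(n):
            if i == k or M[i][k] == 0:
                continue
            f = M[i][k] / pk
            Mi, Mk = M[i], M[k]
            for c in range(k, n + 1):
                Mi[c] -= f * Mk[c]
    return [M[i][n] / M[i][i] for i in range(n)]


def vertex_oracle(lp: LPProblem, max_subsets=300_000) -> OracleResult:
    """Exact optimum of a tiny rational LP by enumerating basic solutions.

    All data must be exactly rational (int/Fraction/mpq; floats convert via
    their binary expansion).  Caps: <= 8 variables and <= 8 rows.  Missing
    bounds are replaced by a huge exact box; an optimum that moves when the
    box is enlarged is reported unbounded.  This routine is deliberately
    independent of the simplex implementation.
    """
    n, m = lp.n_vars, lp.n_rows
    if n > 8 or m > 8:
        raise LPError("vertex_oracle is capped at 8 variables and 8 rows")

    def run(box):
        cons = []  # (coeffs, rhs, kind)
        for i in range(m):
            coeffs = [mpq(0)] * n
            for j, col in enumerate(lp.cols):
                if i in col:
                    coeffs[j] = rat(col[i])
            cons.append((coeffs, rat(lp.rhs[i]), lp.row_senses[i]))
        for j in range(n):
            unit = [mpq(0)] * n
            unit[j] = mpq(1)
            lo = lp.lower[j]
            hi = lp.upper[j]
            cons.append((unit, rat(lo) if isfin(lo) else -box, "ge"))
            cons.append((unit, rat(hi) if isfin(hi) else box, "le"))
        ncons = len(cons)
        if math.comb(ncons, n) > max_subsets:
            raise LPError("vertex_oracle refused: too many active-set candidates")
        cvec = [rat(c) for c in lp.objective]
        want_max = lp.sense == "max"
        best = None
        best_x = None
        feasible = False
        for subset in itertools.combinations(range(ncons), n):
            Arows = [cons[k][0] for k in subset]
            brhs = [cons[k][1] for k in subset]
            x = _solve_exact(Arows, brhs)
            if x is None:
                continue
            ok = True
            for coeffs, rhs, kind in cons:
                v = sum(c * xi for c, xi in zip(coeffs, x))
                if kind == "eq" and v != rhs:
                    ok = False
                elif kind == "ge" and v < rhs:
                    ok = False
                elif kind == "le" and v > rhs:
                    ok = False
                if not ok:
                    break
            if not ok:
                continue
            feasible = True
            obj = sum(c * xi for c, xi in zip(cvec, x))
            if best is None or (obj > best if want_max else obj < best):
                best = obj
                best_x = x
        if not feasible:
            return OracleResult("infeasible", None)
        return OracleResult("optimal", best, best_x)

    r1 = run(_ORACLE_BOX)
    if r1.status == "infeasible":
        return r1
    needs_box = any(not isfin(lp.lower[j]) or not isfin(lp.upper[j])
                    for j in range(n))
    if needs_box:
        r2 = run(_ORACLE_BOX * 4)
        if r2.objective != r1.objective:
            return OracleResult("unbounded", None)
    return r1


# ----------------------------------------------------------------------
# MPS export / import


def _mps_num(x) -> str:
    if isinstance(x, (int,)):
        return str(x)
    try:
        q = rat(x)
    except (TypeError, ValueError):
        return f"{float(x):.17e}"
    s = rat_to_str(q)
    if "/" in s:
        return f"{float(gmpy2.mpfr(q, 200)):.36e}"
    return s


def _sanitize_names(names, prefix):
    seen = {}
    out = []
    for name in names:
        clean = re.sub(r"\s", "_", str(name)) or prefix
        if clean in seen:
            seen[clean] += 1
            newname = f"{clean}_{seen[clean]}"
            logger.warning("MPS name collision: %s renamed to %s", clean, newname)
            clean = newname
        else:
            seen[clean] = 1
        out.append(clean)
    return out


def write_mps(lp: LPProblem, path):
    """Write the LP in MPS format with free-form full-precision numbers."""
    cnames = _sanitize_names(lp.col_names, "C")
    rnames = _sanitize_names(lp.row_names, "R")
    sense_char = {"eq": "E", "ge": "G", "le": "L"}
    lines = ["NAME          QUADME", "OBJSENSE",
             "    " + ("MAX" if lp.sense == "max" else "MIN"), "ROWS",
             " N  OBJ"]
    for i, s in enumerate(lp.row_senses):
        lines.append(f" {sense_char[s]}  {rnames[i]}")
    lines.append("COLUMNS")
    for j in range(lp.n_vars):
        if lp.objective[j] != 0:
            lines.append(f"    {cnames[j]}  OBJ  {_mps_num(lp.objective[j])}")
        for i, a in sorted(lp.cols[j].items()):
            lines.append(f"    {cnames[j]}  {rnames[i]}  {_mps_num(a)}")
    lines.append("RHS")
    for i, b in enumerate(lp.rhs):
        if b != 0:
            lines.append(f"    RHS  {rnames[i]}  {_mps_num(b)}")
    lines.append("BOUNDS")
    for j in range(lp.n_vars):
        lo, hi = lp.lower[j], lp.upper[j]
        if isfin(lo) and isfin(hi) and lo == hi:
            lines.append(f" FX BND  {cnames[j]}  {_mps_num(lo)}")
            continue
        if isfin(lo):
            if lo != 0:
                lines.append(f" LO BND  {cnames[j]}  {_mps_num(lo)}")
        else:
            lines.append(f" MI BND  {cnames[j]}")
        if isfin(hi):
            lines.append(f" UP BND  {cnames[j]}  {_mps_num(hi)}")
    lines.append("ENDATA")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_mps(path) -> LPProblem:
    """Minimal MPS reader covering the dialect written by :func:`write_mps`."""
    sense = "min"
    row_senses, row_names = [], []
    row_index = {}
    col_order, col_index = [], {}
    cols, objective = [], []
    rhs_map = {}
    bounds = {}
    section = None
    with open(path) as fh:
        for rawline in fh:
            line = rawline.rstrip("\n")
            if not line.strip() or line.startswith("*"):
                continue
            if not line[0].isspace():
                section = line.split()[0]
                continue
            toks = line.split()
            if section == "OBJSENSE":
                sense = "max" if toks[0].upper().startswith("MAX") else "min"
            elif section == "ROWS":
                kind, name = toks
                if kind == "N":
                    continue
                row_index[name] = len(row_names)
                row_names.append(name)
                row_senses.append({"E": "eq", "G": "ge", "L": "le"}[kind])
            elif section == "COLUMNS":
                cname = toks[0]
                if cname not in col_index:
                    col_index[cname] = len(col_order)
                    col_order.append(cname)
                    cols.append({})
                    objective.append(mpq(0))
                j = col_index[cname]
                for rname, val in zip(toks[1::2], toks[2::2]):
                    if rname == "OBJ":
                        objective[j] = rat(val)
                    else:
                        cols[j][row_index[rname]] = rat(val)
            elif section == "RHS":
                for rname, val in zip(toks[1::2], toks[2::2]):
                    rhs_map[row_index[rname]] = rat(val)
            elif section == "BOUNDS":
                kind = toks[0]
                cname = toks[2]
                j = col_index[cname]
                lo, hi = bounds.get(j, (mpq(0), INF))
                if kind == "LO":
                    lo = rat(toks[3])
                elif kind == "UP":
                    hi = rat(toks[3])
                elif kind == "FX":
                    lo = hi = rat(toks[3])
                elif kind == "MI":
                    lo = -INF
                elif kind == "PL":
                    hi = INF
                elif kind == "FR":
                    lo, hi = -INF, INF
                bounds[j] = (lo, hi)
    m = len(row_names)
    rhs = [rhs_map.get(i, mpq(0)) for i in range(m)]
    lower = [bounds.get(j, (mpq(0), INF))[0] for j in range(len(col_order))]
    upper = [bounds.get(j, (mpq(0), INF))[1] for j in range(len(col_order))]
    return LPProblem(objective, sense, cols, row_senses, rhs, lower, upper,
                     col_order, row_names)
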