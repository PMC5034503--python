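"""Precision and tolerance contracts shared by every numeric routine.

Two arithmetic modes are supported: native IEEE double precision, and
software extended precision (binary floating point carrying a requested
number of significant decimal digits, 34 by default, which matches IEEE
binary128).  Model data is held in exact rational form (``gmpy2.mpq``)
until it enters a solver, so switching contexts never re-rounds inputs.
"""
from __future__ import annotations

import contextlib
import math
import re
from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction

import gmpy2
from gmpy2 import mpfr, mpq

INF = float("inf")

_MPQ_TYPE = type(mpq())
_MPFR_TYPE = type(mpfr(0))


def is_rational(x) -> bool:
    return isinstance(x, (int, Fraction, _MPQ_TYPE))


def rat(x):
    """Exact rational from int/str/float/Fraction/mpq/mpfr.  Never rounds.

    Strings may be decimal (``"1.5"``, ``"9.35e-14"``) or explicit
    fractions (``"3/7"``).  Floats and mpfr values convert via their exact
    binary expansion.
    """
    if isinstance(x, _MPQ_TYPE):
        return x
    if isinstance(x, bool):
        raise TypeError("bool is not a numeric coefficient")
    if isinstance(x, int):
        return mpq(x)
    if isinstance(x, Fraction):
        return mpq(x.numerator, x.denominator)
    if isinstance(x, float):
        if math.isinf(x) or math.isnan(x):
            raise ValueError("cannot convert non-finite float to a rational")
        return mpq(*x.as_integer_ratio())
    if isinstance(x, _MPFR_TYPE):
        if not gmpy2.is_finite(x):
            raise ValueError("cannot convert non-finite value to a rational")
        return mpq(x)
    if isinstance(x, str):
        s = x.strip()
        if "/" in s:
            num, den = s.split("/", 1)
            return mpq(int(num), int(den))
        f = Fraction(Decimal(s))
        return mpq(f.numerator, f.denominator)
    raise TypeError(f"cannot convert {type(x).__name__} to a rational")


_POW10 = re.compile(r"^-?\d+(\.\d+)?([eE][-+]?\d+)?$")


def rat_to_str(x) -> str:
    """Serialize an exact rational losslessly.

    Values whose denominator is 10-smooth (2^a 5^b) are written as plain
    decimal strings; anything else as an exact ``"p/q"`` fraction.
    """
    q = rat(x)
    den = int(q.denominator)
    num = int(q.numerator)
    if den == 1:
        return str(num)
    d = den
    e2 = 0
    while d % 2 == 0:
        d //= 2
        e2 += 1
    e5 = 0
    while d % 5 == 0:
        d //= 5
        e5 += 1
    if d == 1:
        # scale to a power of ten
        shift = max(e2, e5)
        scaled = num * (5 ** (shift - e5)) * (2 ** (shift - e2))
        s = str(abs(scaled)).rjust(shift + 1, "0")
        out = s[:-shift] + "." + s[-shift:]
        return ("-" if num < 0 else "") + out
    return f"{num}/{den}"


def bound_to_str(x) -> str:
    if isinstance(x, float) and math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return rat_to_str(x)


def bound_from_str(s):
    if s in ("inf", "+inf", "Infinity"):
        return INF
    if s in ("-inf", "-Infinity"):
        return -INF
    return rat(s)


def isfin(x) -> bool:
    """Finite test valid for float, mpfr, mpq and int."""
    if isinstance(x, (int, Fraction, _MPQ_TYPE)):
        return True
    if isinstance(x, float):
        return math.isfinite(x)
    return bool(gmpy2.is_finite(x))


@dataclass(frozen=True)
class ArithmeticContext:
    """Precision/tolerance contract under which all numerics run.

    precision_digits
        Significant decimal digits carried by the solver arithmetic
        (>= 15).  Ignored when ``native`` is true.
    native
        Use the platform double instead of software floats.
    feas_tol, opt_tol
        Feasibility and optimality tolerances used for certification.
    iteration_limit
        Simplex pivot budget per LP solve.
    """

    precision_digits: int = 34
    native: bool = False
    feas_tol: float = 1e-15
    opt_tol: float = 1e-15
    iteration_limit: int = 100_000

    def __post_init__(self):
        if self.precision_digits < 15:
            raise ValueError("precision_digits must be >= 15")
        if not (self.feas_tol > 0 and self.opt_tol > 0):
            raise ValueError("tolerances must be positive")
        if self.iteration_limit <= 0:
            raise ValueError("iteration_limit must be positive")

    @classmethod
    def quad(cls, precision_digits: int = 34, feas_tol: float = 1e-15,
             opt_tol: float = 1e-15, iteration_limit: int = 100_000):
        return cls(precision_digits=precision_digits, native=False,
                   feas_tol=feas_tol, opt_tol=opt_tol,
                   iteration_limit=iteration_limit)

    @classmethod
    def double(cls, feas_tol: float = 1e-9, opt_tol: float = 1e-9,
               iteration_limit: int = 100_000):
        return cls(precision_digits=15, native=True,
                   feas_tol=feas_tol, opt_tol=opt_tol,
                   iteration_limit=iteration_limit)

    @classmethod
    def from_mode(cls, mode: str):
        if mode == "double":
            return cls.double()
        if mode == "quad":
            return cls.quad()
        raise ValueError(f"unknown precision mode {mode!r}")

    @property
    def mode(self) -> str:
        return "double" if self.native else "quad"

    @property
    def precision_bits(self) -> int:
        return int(math.ceil(self.precision_digits * math.log2(10))) + 8

    @contextlib.contextmanager
    def activate(self):
        """Set the working precision of gmpy2 arithmetic for this block."""
        if self.native:
            yield self
            return
        saved = gmpy2.get_context()
        new = saved.copy()
        new.precision = self.precision_bits
        gmpy2.set_context(new)
        try:
            yield self
        finally:
            gmpy2.set_context(saved)

    def num(self, x):
        """Convert a coefficient into this context's working type."""
        if self.native:
            if isinstance(x, float):
                return x
            return float(x)
        if isinstance(x, float) and math.isinf(x):
            return mpfr(x, self.precision_bits)
        if isinstance(x, str):
            return mpfr(rat(x), self.precision_bits)
        if isinstance(x, Fraction):
            return mpfr(mpq(x.numerator, x.denominator), self.precision_bits)
        return mpfr(x, self.precision_bits)

    @property
    def zero(self):
        return 0.0 if self.native else mpfr(0, self.precision_bits)

    @property
    def one(self):
        return 1.0 if self.native else mpfr(1, self.precision_bits)

    @property
    def inf(self):
        return INF

    def pivot_tol(self):
        """Magnitude below which a pivot element is treated as zero."""
        if self.native:
            return 1e-11
        return 10.0 ** (-(self.precision_digits - 6))


DEFAULT_QUAD = ArithmeticContext.quad()
DEFAULT_DOUBLE = ArithmeticContext.double()
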