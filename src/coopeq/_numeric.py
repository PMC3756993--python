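"""Exact-rational helpers shared across the package.

The dilemma families in scope have rational payoffs, and several of the
quantities the solver reports (structure values, deviation probabilities,
equilibrium weights) are asserted as exact equalities downstream.  All core
arithmetic therefore runs on :class:`fractions.Fraction`; floats only appear
at the presentation layer or as a fallback for irrational roots.
"""

from __future__ import annotations

import math
from fractions import Fraction
from numbers import Rational
from typing import Union

Numeric = Union[int, float, str, Fraction]


def to_fraction(x: Numeric) -> Fraction:
    """Convert user input to an exact Fraction.

    Floats are converted through their shortest decimal repr, so 0.2 becomes
    1/5 rather than the binary 3602879701896397/18014398509481984.
    """
    if isinstance(x, Rational):
        return Fraction(x)
    if isinstance(x, float):
        if not math.isfinite(x):
            raise ValueError(f"non-finite payoff {x!r}")
        return Fraction(str(x))
    if isinstance(x, str):
        return Fraction(x)
    raise TypeError(f"cannot interpret {x!r} as a rational number")


def sqrt_exact(x: Fraction) -> Union[Fraction, float]:
    """Square root of a nonnegative Fraction, exact when it is rational.

    Returns a Fraction when ``x`` is a perfect square of a rational, else a
    float.  Equilibrium weights on adjacent-claim supports are square roots of
    rational numbers and are frequently exact (e.g. 1/2).
    """
    if x < 0:
        raise ValueError("sqrt of negative number")
    if x == 0:
        return Fraction(0)
    num, den = x.numerator, x.denominator
    rn, rd = math.isqrt(num), math.isqrt(den)
    if rn * rn == num and rd * rd == den:
        return Fraction(rn, rd)
    return math.sqrt(num / den)


def as_float(x) -> float:
    return float(x)


def fraction_repr(x) -> str:
    """Serialize a number losslessly: 'p/q' for rationals, repr for floats."""
    if isinstance(x, Rational):
        f = Fraction(x)
        return f"{f.numerator}/{f.denominator}"
    return repr(float(x))


def parse_number(s) -> Union[Fraction, float]:
    """Inverse of :func:`fraction_repr`."""
    if isinstance(s, (int, Fraction)):
        return Fraction(s)
    if isinstance(s, float):
        return s
    s = str(s)
    if "/" in s:
        return Fraction(s)
    try:
        return Fraction(s)
    except ValueError:
        return float(s)
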