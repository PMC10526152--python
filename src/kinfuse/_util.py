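"""Shared numeric helpers: exact rounding and fraction (de)serialization."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from numbers import Rational


def round_half_away(value, ndigits: int = 2) -> float:
    """Round half away from zero, matching the convention used for every
    reported probability (e.g. 0.465 -> 0.47, not banker's 0.46).

    Rational inputs are rounded exactly; floats go through their shortest
    decimal repr so that e.g. 0.365 rounds up as a human would expect.
    """
    if isinstance(value, Rational):
        q = Fraction(value) * 10**ndigits
        n, d = q.numerator, q.denominator
        if n >= 0:
            scaled = (2 * n + d) // (2 * d)
        else:
            scaled = -((-2 * n + d) // (2 * d))
        return float(scaled) / 10**ndigits
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def format_fraction(value) -> str:
    """Render an exact rational as ``"p/q"`` (``"p"`` when integral)."""
    f = Fraction(value)
    if f.denominator == 1:
        return str(f.numerator)
    return f"{f.numerator}/{f.denominator}"


def parse_fraction(text) -> Fraction:
    """Parse ``"7/9"``, ``"0.5"`` or a number into an exact Fraction."""
    if isinstance(text, Rational):
        return Fraction(text)
    if isinstance(text, float):
        return Fraction(str(text))
    s = str(text).strip()
    if "/" in s:
        num, den = s.split("/")
        return Fraction(int(num), int(den))
    return Fraction(s)
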