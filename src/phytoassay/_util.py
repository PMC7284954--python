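"""Shared numeric helpers: half-up rounding and exact percentages."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimal places, ties away from zero.

    Python's built-in ``round`` uses banker's rounding; reported index values
    and percentages use the conventional half-up rule instead.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    # repr() gives the shortest decimal string that round-trips, which is the
    # value the experimenter "sees"; quantize that, not the binary expansion.
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 0) -> float | int:
    """Exact percentage ``100*numerator/denominator`` rounded half-up.

    Uses rational arithmetic so integer inputs never suffer float error.
    Returns an ``int`` when ``ndigits == 0``.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for a zero denominator")
    frac = Fraction(100 * numerator, denominator)
    scale = Fraction(10) ** ndigits
    scaled = frac * scale
    # floor(x + 1/2) implements half-up for non-negative x; mirror for negatives
    if scaled >= 0:
        rounded = (scaled + Fraction(1, 2)).__floor__()
    else:
        rounded = -((-scaled + Fraction(1, 2)).__floor__())
    if ndigits == 0:
        return int(rounded)
    return float(Fraction(rounded, scale))
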