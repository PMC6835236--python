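"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed summary tables).

    Python's builtin ``round`` is banker's rounding; printed percentages such
    as 62.395 -> 62.40 require half-away-from-zero.  Decimal quantisation on
    the shortest repr avoids binary-float edge cases like 2.125 -> 2.12.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * numerator / denominator, rounded half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_away(100.0 * numerator / denominator, ndigits)
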