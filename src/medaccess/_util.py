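"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed tables).

    Python's builtin ``round`` is banker's rounding; reported percentages in
    planning tables are conventionally rounded half-up, so 0.125 -> 0.13.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(part: float, total: float, ndigits: int = 2) -> float:
    """100 * part / total, rounded half-up to ``ndigits`` decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * part / total, ndigits)
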