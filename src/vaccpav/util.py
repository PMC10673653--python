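"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed summary
    percentages), unlike Python's bankers rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(part: int | float, total: int | float, precision: int = 0) -> float:
    """``100 * part / total`` rounded half-up to ``precision`` decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * part / total, precision)


def format_percent(part: int | float, total: int | float, precision: int = 0) -> str:
    p = percent(part, total, precision)
    return f"{p:.{precision}f}%"
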