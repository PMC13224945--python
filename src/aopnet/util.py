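"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Summary percentages are reported with half-up rounding (78.125 -> 78.13),
    which is the convention spreadsheets and most reporting tools use, rather
    than Python's default banker's rounding.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(n: int, total: int, ndigits: int = 2) -> float | None:
    """Percentage ``100 * n / total`` rounded half-up; ``None`` if total is 0."""
    if total == 0:
        return None
    return round_half_up(100.0 * n / total, ndigits)
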