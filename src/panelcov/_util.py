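"""Small shared helpers: half-up rounding and percentage formatting."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, the convention clinical reports use.

    Python's built-in ``round`` is banker's rounding; report percentages such
    as 2.35 -> 2.4 must not depend on the parity of the last digit.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: float, total: float, ndigits: int = 1) -> float:
    """Percentage ``100 * count / total`` rounded half-up to `ndigits`."""
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total is undefined")
    return round_half_up(100.0 * count / total, ndigits)
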