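"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for percentages).

    Python's built-in ``round`` is banker's rounding; reported clinical
    percentages conventionally round 0.05 up.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
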