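"""Small shared helpers."""

from __future__ import annotations

import decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero, as printed tables in this field do.

    Python's built-in ``round`` is banker's rounding; composition tables and
    physicochemical summaries are conventionally printed with 0.5 rounding up
    (away from zero), so 11.25 -> 11.3 at one decimal.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)
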