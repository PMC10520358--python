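"""Small shared helpers."""

from __future__ import annotations

import decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as in reported screen tables.

    Python's built-in ``round`` uses banker's rounding; published viability
    and Z-score tables conventionally round half-up, so reports use this.
    """
    q = decimal.Decimal(10) ** -ndigits
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)
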