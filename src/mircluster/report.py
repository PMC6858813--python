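"""Reporting helpers: rounding conventions shared by all table output.

Printed statistics use round-half-away-from-zero (so 6.75 -> 6.8 and
-121.8 -> -122), not banker's rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 0) -> float | int:
    """Round with ties away from zero; returns int when ndigits == 0."""
    q = Decimal(1).scaleb(-ndigits)
    # Decimal's ROUND_HALF_UP is ties-away-from-zero.
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return int(d) if ndigits == 0 else float(d)
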