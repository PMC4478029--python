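"""Small shared helpers: half-up rounding and percent formatting."""

from __future__ import annotations

import math
from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as tables are conventionally printed.

    Python's built-in ``round`` uses banker's rounding; printed prevalence
    triples must be reproducible bit-exactly, so all percent formatting in
    the package goes through this function.
    """
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fmt_pct(x: float, ndigits: int = 1) -> str:
    """Format a percentage half-up at ``ndigits`` decimals, e.g. ``'2.6'``."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{round_half_up(x, ndigits):.{ndigits}f}"
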