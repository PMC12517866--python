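"""Presentation-layer rounding helpers.

Report tables round half-up (so 0.125 -> "0.13" at 2 decimals), matching how
pharmacovigilance summary tables are conventionally printed; banker's
rounding would disagree with published percentage cells.  Rounding is applied
only at presentation — all signal decisions use unrounded values.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero at ``decimals`` places."""
    if value is None or (isinstance(value, float) and not math.isfinite(value)):
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage with half-up rounding; NaN when the denominator is zero."""
    if not denominator:
        return float("nan")
    return round_half_up(100.0 * numerator / denominator, decimals)


def fmt_pct(numerator: float, denominator: float, decimals: int = 2) -> str:
    """Format like the printed tables: ``21.20%``-style, fixed decimals."""
    value = pct(numerator, denominator, decimals)
    return "nan" if math.isnan(value) else f"{value:.{decimals}f}%"
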