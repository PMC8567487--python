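"""Half-away-from-zero rounding, matching how clinical tables are printed."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Python's built-in ``round`` uses banker's rounding; normative tables round
    0.375 to 0.38, -1.25 to -1.3. Decimal arithmetic on ``repr(x)`` avoids
    binary-float artifacts like 2.675 -> 2.67.
    """
    if not math.isfinite(x):
        return x
    d = Decimal(repr(float(x)))
    # absorb binary-float noise (e.g. 0.3749999999999998 for 0.15/0.4) well
    # below any measured precision before resolving the half-way tie
    d = d.quantize(Decimal(1).scaleb(-(ndigits + 9)), rounding=ROUND_HALF_UP)
    return float(d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))
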