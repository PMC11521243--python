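"""Shared numeric conventions: half-up rounding and display truncation.

Published SeDeM tables round half-up at two decimals; the composition table
truncates (does not round) at three decimals. Both conventions are applied
only at the reporting edge — chained computations always use full precision.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (table convention), not banker's rounding."""
    if not math.isfinite(x):
        return x
    # collapse binary representation noise (e.g. 7.084999999999999 for the
    # exact decimal 7.085) before deciding the tie
    x = round(x, ndigits + 6)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def truncate(x: float, ndigits: int = 3) -> float:
    """Drop digits beyond ``ndigits`` without rounding.

    A tiny epsilon guards against binary representation pushing an exact
    decimal value (e.g. 56.242) just below itself.
    """
    if not math.isfinite(x):
        return x
    scale = 10.0**ndigits
    eps = 1e-9
    return math.floor(x * scale + eps) / scale
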