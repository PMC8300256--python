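"""Display rounding helpers.

All statistics are carried at full precision internally; these helpers are
used only at the display boundary. Rounding is half-away-from-zero (the
convention of the printed tables being replicated), not banker's rounding.
"""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties going away from zero.

    >>> round_half_away(0.375, 2)
    0.38
    >>> round_half_away(-2.5)
    -3.0
    """
    if not math.isfinite(x):
        return x
    scale = 10.0 ** ndigits
    scaled = x * scale
    # nudge ties off the representation boundary before floor/ceil
    if scaled >= 0:
        r = math.floor(scaled + 0.5)
    else:
        r = math.ceil(scaled - 0.5)
    return r / scale


def as_percent(fraction: float) -> int:
    """Express a fraction as an integer percent, half away from zero."""
    return int(round_half_away(fraction * 100.0, 0))
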