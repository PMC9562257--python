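"""Shared numeric helpers: rounding conventions and probability validation."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Python's built-in ``round`` uses banker's rounding; clinical tables in
    this package round 0.5 up (and -0.5 down), so the convention is explicit.
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return int(math.ceil(x - 0.5))


def round_display(x: float, ndigits: int = 2) -> float:
    """Round for table display, halves away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def as_percent(p: float) -> int:
    """Whole-percent display value of a probability (half away from zero)."""
    return round_half_away(100.0 * p)


def check_probability(value: float, name: str, *, open_interval: bool = False) -> float:
    value = float(value)
    if open_interval:
        if not 0.0 < value < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1); got {value!r}")
    elif not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1]; got {value!r}")
    return value
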