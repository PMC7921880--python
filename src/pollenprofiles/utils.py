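"""Small shared helpers: date arithmetic on closed intervals and the
round-half-up convention used for every reported figure."""

from __future__ import annotations

import datetime as dt
from decimal import Decimal, ROUND_HALF_UP

ONE_DAY = dt.timedelta(days=1)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (school rounding).

    Python's built-in ``round`` uses banker's rounding, which maps 0.5 to 0;
    reported percentages and means here use half-up instead, so 87.5 -> 88
    and 21.65 -> 21.7.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def daterange(start: dt.date, end: dt.date) -> list[dt.date]:
    """All days of the closed interval [start, end]."""
    if start > end:
        raise ValueError(f"start {start} after end {end}")
    return [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]


def inclusive_days(start: dt.date, end: dt.date) -> int:
    """Length of the closed interval [start, end] in days."""
    if start > end:
        raise ValueError(f"start {start} after end {end}")
    return (end - start).days + 1
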