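"""Inclusive year-range helpers.

A period is an ``(first_year, last_year)`` pair of calendar years CE, both
inclusive — the natural unit for calibration windows, reference periods and
chronology spans.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidSplitError, ValidationError

Period = tuple[int, int]


def validate_period(period: Period, name: str = "period") -> Period:
    first, last = int(period[0]), int(period[1])
    if last < first:
        raise ValidationError(f"{name} ({first}, {last}) is not well ordered")
    return first, last


def period_years(period: Period) -> np.ndarray:
    """All calendar years in the period, inclusive of both ends."""
    first, last = validate_period(period)
    return np.arange(first, last + 1)


def periods_overlap(a: Period, b: Period) -> bool:
    a = validate_period(a)
    b = validate_period(b)
    return a[0] <= b[1] and b[0] <= a[1]


def check_disjoint(cal: Period, ver: Period) -> None:
    """Raise if calibration and verification windows share any year."""
    if periods_overlap(cal, ver):
        raise InvalidSplitError(
            f"calibration {cal} and verification {ver} windows overlap"
        )
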