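"""Period keys for indicator aggregation.

A sales week belongs wholly to the calendar month (or quarter) containing its
week_start date.  Months key as "YYYY-MM", quarters as "YYYYQn"; both sort
chronologically as strings.
"""

from __future__ import annotations

import datetime as dt

import pandas as pd

PERIOD_UNITS = ("month", "quarter")


def period_key(week_start: dt.date | pd.Timestamp, unit: str) -> str:
    ts = pd.Timestamp(week_start)
    if unit == "month":
        return f"{ts.year:04d}-{ts.month:02d}"
    if unit == "quarter":
        return f"{ts.year:04d}Q{(ts.month - 1) // 3 + 1}"
    raise ValueError(f"unknown period unit {unit!r} (expected one of {PERIOD_UNITS})")


def period_range(first: str, last: str, unit: str) -> list[str]:
    """All consecutive period keys from ``first`` to ``last`` inclusive."""
    if unit == "month":
        idx = pd.period_range(first, last, freq="M")
        return [f"{p.year:04d}-{p.month:02d}" for p in idx]
    if unit == "quarter":
        idx = pd.period_range(first.replace("Q", "-Q"), last.replace("Q", "-Q"), freq="Q")
        return [f"{p.year:04d}Q{p.quarter}" for p in idx]
    raise ValueError(f"unknown period unit {unit!r} (expected one of {PERIOD_UNITS})")
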