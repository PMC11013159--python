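"""Comparator series shown alongside a store's indicators.

Three comparator kinds: the unweighted average across all stores with data in
the period (each store-community gets equal voice; an energy-weighted pooled
mean is available behind a flag), the dietary-guideline target (constant
across periods), and a user-set target.  Trend windows re-derive quarterly
values from the pooled base records rather than averaging monthly values,
because the indicator is a ratio and a mean of ratios is not the ratio of
sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .indicators import IndicatorSet, compute_indicator_sets
from .periods import period_key, period_range

COMPARATOR_KINDS = ("all-store-average", "guideline-target", "user-target")


@dataclass
class AverageResult:
    value: float
    n_stores: int

    @property
    def defined(self) -> bool:
        return self.n_stores > 0


def all_store_average(
    sets: list[IndicatorSet],
    period: str,
    indicator_key: str,
    exclude_store: str | None = None,
    energy_weighted: bool = False,
) -> AverageResult:
    """Mean indicator over stores with a defined value in the period.

    Unweighted by default; ``energy_weighted=True`` weights each store by its
    total classified energy (a pooled-basket view).  Stores with no sales in
    the period are omitted; the count of contributing stores is attached.
    """
    values: list[float] = []
    weights: list[float] = []
    for s in sets:
        if s.period != period or s.no_sales:
            continue
        if exclude_store is not None and s.store_id == exclude_store:
            continue
        v = s.value(indicator_key)
        if math.isnan(v):
            continue
        values.append(v)
        weights.append(s.total_energy_kj)
    if not values:
        return AverageResult(math.nan, 0)
    if energy_weighted:
        wsum = sum(weights)
        return AverageResult(sum(v * w for v, w in zip(values, weights)) / wsum, len(values))
    return AverageResult(sum(values) / len(values), len(values))


def all_store_average_series(
    sets: list[IndicatorSet], periods: list[str], indicator_key: str, energy_weighted: bool = False
) -> dict[str, AverageResult]:
    return {p: all_store_average(sets, p, indicator_key, energy_weighted=energy_weighted) for p in periods}


def trend_series(
    quantified: pd.DataFrame,
    store_id: str,
    indicator_key: str,
    window: int,
    period_unit: str = "month",
    reference_energy: float | None = None,
    **indicator_kwargs,
) -> tuple[pd.Series, bool]:
    """Chronological series of the most recent ``window`` periods for a store.

    Values are recomputed from the base weekly records at the requested period
    unit (so a quarterly window pools the quarter's weeks).  Gaps — periods
    inside the span with no sales — appear as NaN.  Returns (series,
    truncated): ``truncated`` is True when fewer periods than requested exist.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    kwargs = dict(indicator_kwargs)
    if reference_energy is not None:
        kwargs["reference_energy"] = reference_energy
    store_q = quantified.loc[quantified["store_id"] == store_id]
    if len(store_q) == 0:
        return pd.Series(dtype=float), True
    sets = compute_indicator_sets(store_q, period_unit=period_unit, **kwargs)
    by_period = {s.period: s.value(indicator_key) for s in sets}
    all_periods = period_range(min(by_period), max(by_period), period_unit)
    shown = all_periods[-window:]
    series = pd.Series({p: by_period.get(p, math.nan) for p in shown}, dtype=float)
    return series, len(all_periods) < window


def guideline_series(target_value: float, periods: list[str]) -> pd.Series:
    """Period-constant comparator at the target value."""
    return pd.Series({p: target_value for p in periods}, dtype=float)
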