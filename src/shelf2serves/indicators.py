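"""Key dietary indicators: energy-normalised serves per person per day.

For each store and period the tool reports the number of serves of each food
group (and unhealthy subgroup and healthiness tier) purchased per 8.9 MJ of
energy purchased — the population-average daily energy requirement — expressed
as serves/person/day.  Energy is the denominator so stores of different sizes
and periods of different lengths are comparable:

    serves/person/day = raw_serves x reference_energy / total_energy

Five-food-group serves come from per-100 g serve factors over
non-discretionary foods only.  Unhealthy Foods serves are energy-defined at
600 kJ per discretionary serve (the Australian Dietary Guidelines' nominal
discretionary serve).  Alcohol and non-food energy never enter numerator or
denominator; energy of unclassifiable foods (no serve factors, not
discretionary) is likewise excluded from the denominator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .periods import period_key
from .reference_data import (
    FIVE_FOOD_GROUPS,
    ClassificationScheme,
    FoodGroup,
    FoodReference,
    HealthinessTier,
    classify_food,
    default_scheme,
)
from .sales_ingest import QUANT_SERVE_COLUMNS

#: kJ defining one discretionary ("unhealthy") serve.
DISCRETIONARY_SERVE_KJ = 600.0
#: Population-weighted average daily energy requirement, kJ/person/day (8.9 MJ).
REFERENCE_ENERGY_KJ = 8900.0

GROUP_KEYS: dict[FoodGroup, str] = {
    FoodGroup.FRUIT: "fruit",
    FoodGroup.VEGETABLES: "vegetables",
    FoodGroup.GRAINS: "breads_cereals",
    FoodGroup.MEAT: "meat_fish_eggs",
    FoodGroup.DAIRY: "dairy",
    FoodGroup.UNHEALTHY: "unhealthy_foods",
}
TIER_KEYS: dict[HealthinessTier, str] = {
    HealthinessTier.BEST: "tier_best_choice",
    HealthinessTier.LESS_HEALTHY: "tier_less_healthy_choice",
    HealthinessTier.UNHEALTHY: "tier_unhealthy_foods",
}
KEY_LABELS: dict[str, str] = {
    **{k: g.value for g, k in GROUP_KEYS.items()},
    **{k: t.value for t, k in TIER_KEYS.items()},
}


def subgroup_key(subgroup_id: str) -> str:
    return f"sub_{subgroup_id}"


def all_indicator_keys(scheme: ClassificationScheme | None = None) -> list[str]:
    """Canonical ordering: 6 groups, 13 subgroups, 3 tiers."""
    scheme = scheme or default_scheme()
    return (
        list(GROUP_KEYS.values())
        + [subgroup_key(s) for s in scheme.subgroups]
        + list(TIER_KEYS.values())
    )


def indicator_label(key: str, scheme: ClassificationScheme | None = None) -> str:
    scheme = scheme or default_scheme()
    if key in KEY_LABELS:
        return KEY_LABELS[key]
    if key.startswith("sub_"):
        return scheme.subgroups.get(key[4:], key[4:])
    return key


def _classified_mask(quantified: pd.DataFrame) -> pd.Series:
    serve_any = quantified[list(QUANT_SERVE_COLUMNS.values())].gt(0).any(axis=1)
    return quantified["is_discretionary"] | serve_any


def total_energy(quantified: pd.DataFrame) -> float:
    """Total classified food energy (kJ); 0 for an empty selection."""
    if len(quantified) == 0:
        return 0.0
    return float(quantified.loc[_classified_mask(quantified), "energy_kj"].sum())


def serves_by_group(
    quantified: pd.DataFrame,
    scheme: ClassificationScheme | None = None,
    discretionary_serve_kj: float = DISCRETIONARY_SERVE_KJ,
) -> dict[str, float]:
    """Raw (un-normalised) serves per group, subgroup and tier.

    Five-food-group serves sum grams x serve_factor/100 over non-discretionary
    foods; Unhealthy Foods serves are discretionary energy / 600 kJ; subgroup
    serves partition the subgrouped part of that energy; tier serves sum the
    five-group serves of each tier's member foods.
    """
    scheme = scheme or default_scheme()
    out: dict[str, float] = {}
    for g in FIVE_FOOD_GROUPS:
        out[GROUP_KEYS[g]] = float(quantified[QUANT_SERVE_COLUMNS[g]].sum()) if len(quantified) else 0.0

    disc = quantified.loc[quantified["is_discretionary"]] if len(quantified) else quantified
    disc_energy = float(disc["energy_kj"].sum()) if len(disc) else 0.0
    out[GROUP_KEYS[FoodGroup.UNHEALTHY]] = disc_energy / discretionary_serve_kj

    for sid in scheme.subgroups:
        if len(disc):
            e = float(disc.loc[disc["unhealthy_subgroup"] == sid, "energy_kj"].sum())
        else:
            e = 0.0
        out[subgroup_key(sid)] = e / discretionary_serve_kj

    for tier, key in TIER_KEYS.items():
        if tier is HealthinessTier.UNHEALTHY:
            out[key] = out[GROUP_KEYS[FoodGroup.UNHEALTHY]]
        elif len(quantified):
            member = quantified.loc[quantified["tier"] == tier.value]
            out[key] = float(member[list(QUANT_SERVE_COLUMNS.values())].to_numpy().sum())
        else:
            out[key] = 0.0
    return out


def normalize_to_person_day(
    raw_serves: float, total_energy_kj: float, reference_energy: float = REFERENCE_ENERGY_KJ
) -> float:
    """Scale raw serves to serves/person/day at the reference daily energy.

    Returns NaN (the undefined-indicator signal) when total energy is zero;
    reports render that as "no data" rather than dividing by zero.
    """
    if total_energy_kj <= 0:
        return math.nan
    return raw_serves * reference_energy / total_energy_kj


def discretionary_coverage(quantified: pd.DataFrame) -> tuple[float, bool]:
    """Share of discretionary energy captured by the named unhealthy subgroups.

    Returns (fraction, defined).  Undefined (NaN, False) when the selection
    contains no discretionary energy.
    """
    if len(quantified) == 0:
        return math.nan, False
    disc = quantified.loc[quantified["is_discretionary"]]
    denom = float(disc["energy_kj"].sum())
    if denom <= 0:
        return math.nan, False
    covered = float(disc.loc[disc["unhealthy_subgroup"].notna(), "energy_kj"].sum())
    return covered / denom, True


def dollar_share_by_group(
    quantified: pd.DataFrame, reference: FoodReference
) -> Optional[dict[str, float]]:
    """Fraction of classified food dollars per primary food group.

    Shares sum to 1 over classified food dollars; None when those dollars are
    zero.  An optional auxiliary output retained from earlier dollar-based
    store reporting.
    """
    if len(quantified) == 0:
        return None
    groups = {
        code: classify_food(reference[code]).group for code in quantified["food_code"].unique()
    }
    mapped = quantified["food_code"].map(groups)
    ok = mapped.notna()
    total = float(quantified.loc[ok, "dollars"].sum())
    if total <= 0:
        return None
    shares = {k: 0.0 for k in GROUP_KEYS.values()}
    for g, sub in quantified.loc[ok].groupby(mapped[ok]):
        shares[GROUP_KEYS[g]] = float(sub["dollars"].sum()) / total
    return shares


@dataclass
class IndicatorSet:
    """All indicators for one store and one period."""

    store_id: str
    period: str
    total_energy_kj: float
    serves_per_person_day: dict[str, float]
    reference_energy: float = REFERENCE_ENERGY_KJ
    dollar_share: Optional[dict[str, float]] = None
    dollars_total: float = 0.0
    no_sales: bool = False

    def value(self, key: str) -> float:
        return self.serves_per_person_day.get(key, math.nan)


def compute_indicator_sets(
    quantified: pd.DataFrame,
    period_unit: str = "month",
    reference_energy: float = REFERENCE_ENERGY_KJ,
    discretionary_serve_kj: float = DISCRETIONARY_SERVE_KJ,
    scheme: ClassificationScheme | None = None,
    with_dollar_share: bool = False,
    reference: FoodReference | None = None,
) -> list[IndicatorSet]:
    """Compute per store x period indicator sets from quantified sales."""
    scheme = scheme or default_scheme()
    if len(quantified) == 0:
        return []
    df = quantified.copy()
    df["period"] = [period_key(d, period_unit) for d in df["week_start"]]
    sets: list[IndicatorSet] = []
    for (store, period), sub in df.groupby(["store_id", "period"], sort=True):
        energy = total_energy(sub)
        raw = serves_by_group(sub, scheme, discretionary_serve_kj)
        serves = {
            k: normalize_to_person_day(v, energy, reference_energy) for k, v in raw.items()
        }
        share = dollar_share_by_group(sub, reference) if (with_dollar_share and reference) else None
        sets.append(
            IndicatorSet(
                store_id=store,
                period=period,
                total_energy_kj=energy,
                serves_per_person_day=serves,
                reference_energy=reference_energy,
                dollar_share=share,
                dollars_total=float(sub["dollars"].sum()),
                no_sales=energy <= 0,
            )
        )
    return sets


def indicator_table(sets: list[IndicatorSet], scheme: ClassificationScheme | None = None) -> pd.DataFrame:
    """Tidy indicator frame: store_id, period, indicator_key, value, unit."""
    scheme = scheme or default_scheme()
    keys = all_indicator_keys(scheme)
    rows = []
    for s in sets:
        rows.append((s.store_id, s.period, "total_energy", s.total_energy_kj, "kJ"))
        for k in keys:
            rows.append((s.store_id, s.period, k, s.value(k), "serves/person/day"))
        if s.dollar_share:
            for k, v in s.dollar_share.items():
                rows.append((s.store_id, s.period, f"dollar_share_{k}", v, "fraction"))
    return pd.DataFrame(rows, columns=["store_id", "period", "indicator_key", "value", "unit"])


def write_indicators(sets: list[IndicatorSet], csv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Write the tidy CSV (and optionally a JSON payload); both round-trip."""
    table = indicator_table(sets)
    table.to_csv(csv_path, index=False, float_format="%.12g")
    if json_path is not None:
        payload = [
            {
                "store_id": s.store_id,
                "period": s.period,
                "total_energy_kj": s.total_energy_kj,
                "reference_energy": s.reference_energy,
                "serves_per_person_day": {
                    k: (None if math.isnan(v) else v) for k, v in s.serves_per_person_day.items()
                },
                "dollar_share": s.dollar_share,
                "dollars_total": s.dollars_total,
                "no_sales": s.no_sales,
            }
            for s in sets
        ]
        Path(json_path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_indicators(csv_path: str | Path) -> pd.DataFrame:
    """Read a tidy indicator CSV back."""
    return pd.read_csv(csv_path, dtype={"store_id": str, "period": str})


def pivot_indicators(table: pd.DataFrame) -> pd.DataFrame:
    """Wide view: one row per store x period, one column per indicator key."""
    return table.pivot_table(
        index=["store_id", "period"], columns="indicator_key", values="value", aggfunc="first"
    )
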