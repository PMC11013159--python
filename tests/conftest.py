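"""Shared fixtures and the independent brute-force indicator oracle."""

from __future__ import annotations

import math
from collections import defaultdict

import pandas as pd
import pytest

from shelf2serves.periods import period_key
from shelf2serves.reference_data import (
    FIVE_FOOD_GROUPS,
    FoodReference,
    HealthinessTier,
    default_scheme,
)
from shelf2serves.synthetic import generate_reference_fixture


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def fixture_pair(scheme):
    return generate_reference_fixture(scheme)


@pytest.fixture(scope="session")
def reference(fixture_pair) -> FoodReference:
    return fixture_pair[0]


@pytest.fixture(scope="session")
def catalog(fixture_pair) -> pd.DataFrame:
    return fixture_pair[1]


def oracle_indicators(
    sales: pd.DataFrame,
    catalog: pd.DataFrame,
    reference: FoodReference,
    period_unit: str = "month",
    reference_energy: float = 8900.0,
    discretionary_serve_kj: float = 600.0,
) -> dict[tuple[str, str], dict[str, float]]:
    """Explicit per-record recomputation of every indicator.

    Deliberately uses plain Python loops and dicts (no pandas aggregation) so
    it is an independent check on the pipeline: for each sale, convert to
    grams and kJ, accumulate five-group serves over non-discretionary foods,
    energy-defined unhealthy serves over discretionary foods, subgroup and
    tier totals, then normalise by classified energy.
    """
    cat = {}
    for _, row in catalog.iterrows():
        code = row["food_code"]
        if code is None or (isinstance(code, float) and math.isnan(code)):
            code = None
        cat[row["product_id"]] = (float(row["pack_size_g"]), code)

    acc: dict[tuple[str, str], dict] = defaultdict(
        lambda: {"energy": 0.0, "serves": defaultdict(float)}
    )
    tier_keys = {
        HealthinessTier.BEST: "tier_best_choice",
        HealthinessTier.LESS_HEALTHY: "tier_less_healthy_choice",
        HealthinessTier.UNHEALTHY: "tier_unhealthy_foods",
    }
    group_keys = {
        g: k for g, k in zip(
            FIVE_FOOD_GROUPS,
            ["fruit", "vegetables", "breads_cereals", "meat_fish_eggs", "dairy"],
        )
    }
    for _, row in sales.iterrows():
        pid = row["product_id"]
        if pid not in cat:
            continue
        pack, code = cat[pid]
        if code is None or code not in reference:
            continue
        rec = reference[code]
        if rec.is_alcohol:
            continue
        grams = float(row["units_sold"]) * pack
        energy = grams * rec.energy_density / 100.0
        classifiable = rec.is_discretionary or any(
            rec.serve_factor(g) > 0 for g in FIVE_FOOD_GROUPS
        )
        if not classifiable:
            continue
        key = (str(row["store_id"]), period_key(row["week_start"], period_unit))
        cell = acc[key]
        cell["energy"] += energy
        if rec.is_discretionary:
            serves = energy / discretionary_serve_kj
            cell["serves"]["unhealthy_foods"] += serves
            cell["serves"]["tier_unhealthy_foods"] += serves
            if rec.unhealthy_subgroup:
                cell["serves"][f"sub_{rec.unhealthy_subgroup}"] += serves
        else:
            for g in FIVE_FOOD_GROUPS:
                s = grams * rec.serve_factor(g) / 100.0
                if s:
                    cell["serves"][group_keys[g]] += s
                    cell["serves"][tier_keys[rec.tier]] += s

    out: dict[tuple[str, str], dict[str, float]] = {}
    for key, cell in acc.items():
        e = cell["energy"]
        out[key] = {
            k: (v * reference_energy / e if e > 0 else math.nan)
            for k, v in cell["serves"].items()
        }
        out[key]["total_energy"] = e
    return out
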