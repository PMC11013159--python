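"""Synthetic multi-store weekly POS streams with known ground-truth indicators.

Real remote-store sales data are ethically restricted, so every pipeline stage
is exercised against generated data.  The generator works backwards from the
desired serves/person/day: it fixes a weekly energy budget, solves the linear
serve equations to allocate energy and grams across fixture foods, and then
applies multiplicative weekly volume noise.  Whole-week lognormal scaling is
indicator-neutral (the indicator is a ratio), so the noise-free component of
every week reproduces the requested indicator values exactly; an optional
per-product jitter creates indicator-level variability with the requested
values as expectation.

The food fixture spans all six groups, all three healthiness tiers and all 13
unhealthy subgroups, plus an alcohol item, a non-food catalogue item, an
unclassifiable zero-serve food, and the classification edge cases (100% fruit
juice and high-fibre white bread as Less Healthy Choices).
"""

from __future__ import annotations

import datetime as dt
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .indicators import (
    DISCRETIONARY_SERVE_KJ,
    GROUP_KEYS,
    REFERENCE_ENERGY_KJ,
    TIER_KEYS,
    all_indicator_keys,
    subgroup_key,
)
from .reference_data import (
    FIVE_FOOD_GROUPS,
    ClassificationScheme,
    FoodGroup,
    FoodReference,
    FoodReferenceRecord,
    HealthinessTier,
    default_scheme,
)
from .sales_ingest import CATALOG_COLUMNS, SALES_COLUMNS


class GenerationError(ValueError):
    """Raised when a scenario's target indicators cannot be realised."""


#: Typical remote-store conditions used when a scenario leaves a group
#: unspecified: five-food-group purchases sit below guideline targets while
#: discretionary purchases run well above the <=2.5 serves recommendation.
DEMO_TARGETS: dict[str, float] = {
    "fruit": 1.0,
    "vegetables": 2.5,
    "breads_cereals": 4.5,
    "meat_fish_eggs": 2.0,
    "dairy": 1.5,
    "unhealthy_foods": 6.0,
}


class ScenarioSpec(BaseModel):
    """Parameters of a synthetic sales stream."""

    n_stores: int = Field(default=3, ge=1)
    n_weeks: int = Field(default=26, ge=1)
    target_indicators: dict[str, float] = Field(default_factory=dict)
    noise: float = Field(default=0.0, ge=0, description="weekly lognormal volume sigma")
    product_jitter: float = Field(default=0.0, ge=0, description="per-product weekly lognormal sigma")
    seed: int = 0
    weekly_energy_kj: float = Field(default=6_230_000.0, gt=0, description="~100 person-days at 8.9 MJ x 7")
    subgroup_coverage: float = Field(default=0.877, ge=0, le=1,
                                     description="share of discretionary energy in named subgroups")
    start_date: dt.date = dt.date(2024, 1, 1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump(mode="json")
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


# (code, description, kJ/100g, {group: serves/100g}, tier, subgroup, alcohol)
_B, _L, _U = HealthinessTier.BEST, HealthinessTier.LESS_HEALTHY, HealthinessTier.UNHEALTHY
_FIXTURE_FOODS: list[tuple] = [
    ("F001", "Apple, fresh", 250.0, {FoodGroup.FRUIT: 0.667}, _B, None, False),
    ("F002", "Banana, fresh", 370.0, {FoodGroup.FRUIT: 0.667}, _B, None, False),
    ("F003", "Orange, fresh", 180.0, {FoodGroup.FRUIT: 0.667}, _B, None, False),
    ("F004", "Fruit juice, 100% apple", 180.0, {FoodGroup.FRUIT: 0.8}, _L, None, False),
    ("F005", "Dried fruit, sultanas", 1360.0, {FoodGroup.FRUIT: 3.333}, _L, None, False),
    ("F006", "Tinned fruit in syrup", 400.0, {FoodGroup.FRUIT: 0.667}, _L, None, False),
    ("V001", "Frozen mixed vegetables", 150.0, {FoodGroup.VEGETABLES: 1.333}, _B, None, False),
    ("V002", "Carrot, fresh", 140.0, {FoodGroup.VEGETABLES: 1.333}, _B, None, False),
    ("V003", "Potato, fresh", 320.0, {FoodGroup.VEGETABLES: 1.333}, _B, None, False),
    ("V004", "Tinned vegetables, salted", 130.0, {FoodGroup.VEGETABLES: 1.333}, _L, None, False),
    ("V005", "Pumpkin, fresh", 160.0, {FoodGroup.VEGETABLES: 1.333}, _B, None, False),
    ("G001", "Bread, wholemeal loaf", 980.0, {FoodGroup.GRAINS: 2.5}, _B, None, False),
    ("G002", "Rice, white, dry", 1530.0, {FoodGroup.GRAINS: 2.0}, _L, None, False),
    ("G003", "Bread, white, high-fibre", 1050.0, {FoodGroup.GRAINS: 2.5}, _L, None, False),
    ("G004", "Bread, white, regular", 1060.0, {FoodGroup.GRAINS: 2.5}, _L, None, False),
    ("G005", "Breakfast cereal, wholegrain", 1500.0, {FoodGroup.GRAINS: 3.333}, _B, None, False),
    ("G006", "Flour, plain white", 1480.0, {FoodGroup.GRAINS: 2.857}, _L, None, False),
    ("M001", "Beef mince, lean", 800.0, {FoodGroup.MEAT: 1.538}, _B, None, False),
    ("M002", "Eggs, dozen", 550.0, {FoodGroup.MEAT: 0.833}, _B, None, False),
    ("M003", "Corned beef, tinned", 950.0, {FoodGroup.MEAT: 1.0}, _L, None, False),
    ("M004", "Tuna, tinned in brine", 450.0, {FoodGroup.MEAT: 1.0}, _B, None, False),
    ("M005", "Chicken pieces", 700.0, {FoodGroup.MEAT: 1.25}, _B, None, False),
    ("D001", "Milk, skim UHT", 150.0, {FoodGroup.DAIRY: 0.4}, _B, None, False),
    ("D002", "Milk, full cream UHT", 270.0, {FoodGroup.DAIRY: 0.4}, _L, None, False),
    ("D003", "Cheese, cheddar block", 1650.0, {FoodGroup.DAIRY: 2.5}, _B, None, False),
    ("D004", "Yoghurt, natural", 380.0, {FoodGroup.DAIRY: 0.5}, _B, None, False),
    ("T001", "Tea bags", 10.0, {}, _B, None, False),  # unclassifiable: no serves
    ("U001", "Cola soft drink", 180.0, {}, _U, "sugar_sweetened_beverages", False),
    ("U002", "Fruit drink cordial", 200.0, {}, _U, "cordials_fruit_drinks", False),
    ("U003", "Chocolate block", 2200.0, {}, _U, "confectionery", False),
    ("U004", "Sweet biscuits", 2000.0, {}, _U, "sweet_biscuits", False),
    ("U005", "Iced cake bar", 1600.0, {}, _U, "cakes_muffins", False),
    ("U006", "Ice cream tub", 880.0, {}, _U, "ice_cream_desserts", False),
    ("U007", "Potato crisps", 2200.0, {}, _U, "savoury_snacks", False),
    ("U008", "Meat pie, frozen", 1100.0, {}, _U, "savoury_pastries", False),
    ("U009", "Hot chips, takeaway", 1000.0, {}, _U, "takeaway_fried_foods", False),
    ("U010", "Sausages, devon", 1250.0, {}, _U, "processed_meats", False),
    ("U011", "White sugar", 1700.0, {}, _U, "table_sugar", False),
    ("U012", "Strawberry jam", 1100.0, {}, _U, "sweet_spreads", False),
    ("U013", "Tomato sauce", 450.0, {}, _U, "sauces_condiments", False),
    ("U014", "Instant noodles", 1900.0, {}, _U, None, False),  # discretionary, no subgroup
    ("A001", "Beer, full strength", 150.0, {}, _U, None, True),
]

#: Per-group (low, high) foods the allocator splits serves across.  Their
#: kJ-per-serve spread is what lets a basket hit an arbitrary energy total.
_GENERATOR_PAIRS: dict[FoodGroup, tuple[str, str]] = {
    FoodGroup.FRUIT: ("F001", "F006"),
    FoodGroup.VEGETABLES: ("V001", "V003"),
    FoodGroup.GRAINS: ("G001", "G002"),
    FoodGroup.MEAT: ("M004", "M003"),
    FoodGroup.DAIRY: ("D001", "D002"),
}

_PACK_SIZES: dict[str, float] = {
    "F001": 1000, "F002": 1000, "F003": 1000, "F004": 1000, "F005": 375, "F006": 825,
    "V001": 1000, "V002": 1000, "V003": 2000, "V004": 420, "V005": 1500,
    "G001": 700, "G002": 1000, "G003": 700, "G004": 700, "G005": 500, "G006": 1000,
    "M001": 500, "M002": 700, "M003": 340, "M004": 185, "M005": 1000,
    "D001": 1000, "D002": 1000, "D003": 500, "D004": 1000,
    "T001": 100, "U001": 1250, "U002": 1000, "U003": 250, "U004": 250, "U005": 350,
    "U006": 2000, "U007": 175, "U008": 700, "U009": 400, "U010": 500, "U011": 1000,
    "U012": 500, "U013": 500, "U014": 425, "A001": 375,
}


def generate_reference_fixture(
    scheme: ClassificationScheme | None = None,
) -> tuple[FoodReference, pd.DataFrame]:
    """Build the packaged food reference and product catalogue.

    Covers all 6 groups, 3 tiers and 13 subgroups, plus an alcohol item and a
    non-food catalogue entry; every record passes reference validation.
    """
    scheme = scheme or default_scheme()
    records = []
    for code, desc, ed, factors, tier, sub, alcohol in _FIXTURE_FOODS:
        records.append(
            FoodReferenceRecord(
                food_code=code,
                description=desc,
                energy_density=ed,
                serve_factors=factors,
                is_discretionary=(tier is HealthinessTier.UNHEALTHY),
                unhealthy_subgroup=sub,
                tier=tier,
                is_alcohol=alcohol,
            )
        )
    reference = FoodReference(records, scheme)
    cat_rows = [
        {
            "product_id": f"P_{code}",
            "description": desc,
            "pack_size_g": _PACK_SIZES[code],
            "food_code": code,
        }
        for code, desc, *_ in _FIXTURE_FOODS
    ]
    cat_rows.append({"product_id": "N001", "description": "Laundry soap", "pack_size_g": 500, "food_code": None})
    catalog = pd.DataFrame(cat_rows, columns=CATALOG_COLUMNS)
    return reference, catalog


def _resolve_targets(spec: ScenarioSpec) -> tuple[dict[str, float], dict[str, float]]:
    """Split requested indicators into group targets and explicit subgroup targets."""
    groups = dict(DEMO_TARGETS)
    subs: dict[str, float] = {}
    for key, val in spec.target_indicators.items():
        if val < 0:
            raise GenerationError(f"negative target for {key!r}")
        if key in groups:
            groups[key] = float(val)
        elif key.startswith("sub_"):
            subs[key[4:]] = float(val)
        else:
            raise GenerationError(
                f"unsupported target key {key!r}: give one of the six group keys or sub_<id>"
            )
    return groups, subs


def _allocate(
    spec: ScenarioSpec, reference: FoodReference, scheme: ClassificationScheme
) -> tuple[dict[str, float], dict[str, float]]:
    """Solve for grams of each food per 8.9 MJ of basket energy.

    Returns (grams per food per reference-energy unit, ground-truth
    indicator values).  Raises GenerationError when the requested serves
    cannot compose a basket of exactly the reference energy.
    """
    groups, subs = _resolve_targets(spec)
    unit = REFERENCE_ENERGY_KJ
    u = groups["unhealthy_foods"]
    e_disc = u * DISCRETIONARY_SERVE_KJ
    e_core_needed = unit - e_disc
    if e_core_needed < -1e-9:
        raise GenerationError(
            f"unhealthy_foods target {u} alone exceeds the energy budget "
            f"(max {unit / DISCRETIONARY_SERVE_KJ:.2f} serves)"
        )

    # kJ per serve of each generator food
    def kj_per_serve(code: str, group: FoodGroup) -> float:
        rec = reference[code]
        f = rec.serve_factor(group)
        if f <= 0:
            raise GenerationError(f"fixture food {code} has no {group.value} serve factor")
        return rec.energy_density / f

    serves = {g: groups[GROUP_KEYS[g]] for g in FIVE_FOOD_GROUPS}
    for g, s in serves.items():
        if s > 0 and g not in _GENERATOR_PAIRS:
            raise GenerationError(f"no generator foods for group {g.value}")
    lo = {g: kj_per_serve(_GENERATOR_PAIRS[g][0], g) for g in FIVE_FOOD_GROUPS}
    hi = {g: kj_per_serve(_GENERATOR_PAIRS[g][1], g) for g in FIVE_FOOD_GROUPS}
    e_min = sum(serves[g] * lo[g] for g in FIVE_FOOD_GROUPS)
    e_max = sum(serves[g] * hi[g] for g in FIVE_FOOD_GROUPS)
    if not (e_min - 1e-6 <= e_core_needed <= e_max + 1e-6):
        lo_u = (unit - e_max) / DISCRETIONARY_SERVE_KJ
        hi_u = (unit - e_min) / DISCRETIONARY_SERVE_KJ
        raise GenerationError(
            "targets are unachievable with the fixture foods: five-food-group "
            f"serves need {e_core_needed:.0f} kJ of core energy but only "
            f"[{e_min:.0f}, {e_max:.0f}] kJ is composable; with these serves the "
            f"unhealthy_foods target must lie in [{max(lo_u, 0):.2f}, {hi_u:.2f}]"
        )
    t = 0.0 if e_max == e_min else min(max((e_core_needed - e_min) / (e_max - e_min), 0.0), 1.0)

    grams: dict[str, float] = {}
    for g in FIVE_FOOD_GROUPS:
        s = serves[g]
        if s <= 0:
            continue
        low_code, high_code = _GENERATOR_PAIRS[g]
        for code, share in ((low_code, (1.0 - t) * s), (high_code, t * s)):
            if share <= 0:
                continue
            f = reference[code].serve_factor(g)
            grams[code] = grams.get(code, 0.0) + share * 100.0 / f

    # discretionary energy: explicit subgroup targets first, then fill the
    # named subgroups up to the coverage share, remainder to the
    # non-subgrouped discretionary food
    sub_energy: dict[str, float] = {}
    explicit = 0.0
    for sid, s_val in subs.items():
        if sid not in scheme.subgroups:
            raise GenerationError(f"unknown subgroup {sid!r}")
        sub_energy[sid] = s_val * DISCRETIONARY_SERVE_KJ
        explicit += sub_energy[sid]
    if explicit > e_disc + 1e-9:
        raise GenerationError("subgroup targets exceed the unhealthy_foods target")
    covered_target = max(spec.subgroup_coverage * e_disc, explicit)
    rest_subs = [s for s in scheme.subgroups if s not in subs]
    fill = covered_target - explicit
    if fill > 0 and rest_subs:
        for sid in rest_subs:
            sub_energy[sid] = fill / len(rest_subs)
    covered = sum(sub_energy.values())
    uncovered = e_disc - covered

    sub_foods = {
        rec.unhealthy_subgroup: rec
        for rec in reference.records()
        if rec.is_discretionary and rec.unhealthy_subgroup and not rec.is_alcohol
    }
    other = [
        rec for rec in reference.records()
        if rec.is_discretionary and rec.unhealthy_subgroup is None and not rec.is_alcohol
    ]
    for sid, e in sub_energy.items():
        if e <= 0:
            continue
        if sid not in sub_foods:
            raise GenerationError(f"no fixture food for subgroup {sid!r}")
        rec = sub_foods[sid]
        grams[rec.food_code] = grams.get(rec.food_code, 0.0) + e * 100.0 / rec.energy_density
    if uncovered > 1e-9:
        if not other:
            raise GenerationError("no non-subgrouped discretionary food to carry uncovered energy")
        rec = other[0]
        grams[rec.food_code] = grams.get(rec.food_code, 0.0) + uncovered * 100.0 / rec.energy_density

    # ground truth for every indicator key
    truth = {k: 0.0 for k in all_indicator_keys(scheme)}
    truth.update({GROUP_KEYS[g]: serves[g] for g in FIVE_FOOD_GROUPS})
    truth[GROUP_KEYS[FoodGroup.UNHEALTHY]] = u
    for sid, e in sub_energy.items():
        truth[subgroup_key(sid)] = e / DISCRETIONARY_SERVE_KJ
    for g in FIVE_FOOD_GROUPS:
        low_code, high_code = _GENERATOR_PAIRS[g]
        for code, share in ((low_code, (1.0 - t) * serves[g]), (high_code, t * serves[g])):
            truth[TIER_KEYS[reference[code].tier]] += share
    truth[TIER_KEYS[HealthinessTier.UNHEALTHY]] = u
    truth["discretionary_coverage"] = covered / e_disc if e_disc > 0 else math.nan
    return grams, truth


def generate_sales(
    spec: ScenarioSpec,
    reference: FoodReference | None = None,
    catalog: pd.DataFrame | None = None,
    scheme: ClassificationScheme | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Emit a weekly sales stream realising the scenario's indicators.

    Returns (sales frame in the ingest CSV dialect, ground-truth indicator
    values).  Noise-free streams reproduce the ground truth exactly; with
    weekly volume noise the ground truth still holds exactly for ratio
    indicators (whole-week scaling cancels); per-product jitter makes it hold
    in expectation only.  A fixed seed fixes the stream byte-for-byte.
    """
    scheme = scheme or default_scheme()
    if reference is None or catalog is None:
        reference, catalog = generate_reference_fixture(scheme)
    grams_per_unit, truth = _allocate(spec, reference, scheme)

    code_to_product = {
        row["food_code"]: row["product_id"]
        for _, row in catalog.iterrows()
        if row["food_code"] is not None and not (isinstance(row["food_code"], float) and np.isnan(row["food_code"]))
    }
    pack = catalog.set_index("product_id")["pack_size_g"]
    # deterministic unit prices (dollars are reported but not indicator inputs)
    prices = {pid: round(2.0 + (i % 9) * 0.75, 2) for i, pid in enumerate(sorted(pack.index))}

    scale = spec.weekly_energy_kj / REFERENCE_ENERGY_KJ
    base_units = {}
    for code, g in grams_per_unit.items():
        pid = code_to_product[code]
        base_units[pid] = g * scale / float(pack[pid])

    rng = np.random.default_rng(spec.seed)
    rows = []
    product_ids = sorted(base_units)
    for s in range(spec.n_stores):
        store = f"store_{s + 1:02d}"
        for w in range(spec.n_weeks):
            week = spec.start_date + dt.timedelta(weeks=w)
            vol = 1.0
            if spec.noise > 0:
                vol = math.exp(rng.normal(0.0, spec.noise) - spec.noise**2 / 2.0)
            for pid in product_ids:
                jit = 1.0
                if spec.product_jitter > 0:
                    jit = math.exp(rng.normal(0.0, spec.product_jitter) - spec.product_jitter**2 / 2.0)
                units = base_units[pid] * vol * jit
                rows.append((store, week.isoformat(), pid, units, round(units * prices[pid], 2)))
            # non-indicator rows exercising the exclusion paths
            rows.append((store, week.isoformat(), "N001", 10.0 * vol, round(10.0 * vol * prices["N001"], 2)))
            rows.append((store, week.isoformat(), "P_A001", 24.0 * vol, round(24.0 * vol * prices["P_A001"], 2)))
    sales = pd.DataFrame(rows, columns=SALES_COLUMNS)
    truth["weekly_energy_kj"] = spec.weekly_energy_kj
    return sales, truth


def random_scenario(
    rng: np.random.Generator,
    n_stores: int = 2,
    n_weeks: int = 4,
    noise: float = 0.0,
) -> ScenarioSpec:
    """Draw an achievable scenario: five-group serves around typical store
    levels, then an unhealthy target inside the composable energy interval
    (intersected with the observed 2-9 serves/person/day range)."""
    reference, _ = generate_reference_fixture()
    targets = {
        "fruit": rng.uniform(0.5, 2.0),
        "vegetables": rng.uniform(1.5, 3.5),
        "breads_cereals": rng.uniform(3.5, 5.5),
        "meat_fish_eggs": rng.uniform(1.5, 2.5),
        "dairy": rng.uniform(1.0, 2.0),
    }
    serves = {g: targets[GROUP_KEYS[g]] for g in FIVE_FOOD_GROUPS}
    lo_e = hi_e = 0.0
    for g in FIVE_FOOD_GROUPS:
        low_code, high_code = _GENERATOR_PAIRS[g]
        lo_e += serves[g] * reference[low_code].energy_density / reference[low_code].serve_factor(g)
        hi_e += serves[g] * reference[high_code].energy_density / reference[high_code].serve_factor(g)
    u_lo = max((REFERENCE_ENERGY_KJ - hi_e) / DISCRETIONARY_SERVE_KJ, 2.0)
    u_hi = min((REFERENCE_ENERGY_KJ - lo_e) / DISCRETIONARY_SERVE_KJ, 9.0)
    margin = 0.02 * (u_hi - u_lo)
    targets["unhealthy_foods"] = rng.uniform(u_lo + margin, u_hi - margin)
    return ScenarioSpec(
        n_stores=n_stores,
        n_weeks=n_weeks,
        target_indicators=targets,
        noise=noise,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
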