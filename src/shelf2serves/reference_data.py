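"""Food classification reference: groups, tiers, subgroups and the food table.

The indicator taxonomy follows the Australian Dietary Guidelines: five core
food groups (Fruit; Vegetables; Breads and Cereals; Meat, Fish and Eggs;
Dairy) plus a sixth "Unhealthy Foods" group holding discretionary foods.
Within the five groups every food sits in one of two healthiness tiers
("Best Choice" / "Less Healthy Choice"); discretionary foods form the third
tier ("Unhealthy Foods") and may carry one of 13 unhealthy subgroups chosen
as the biggest contributors to discretionary energy in remote-store sales.

A food reference record stores per-100 g serve factors for each of the five
groups, an energy density, and the discretionary/alcohol flags.  Discretionary
foods are barred from contributing serves to the five groups (the potato in
deep-fried hot chips does not count as vegetables here), and alcohol is
excluded from the data wholesale.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator


class FoodGroup(str, enum.Enum):
    """The six top-level food groups reported on."""

    FRUIT = "Fruit"
    VEGETABLES = "Vegetables"
    GRAINS = "Breads and Cereals"
    MEAT = "Meat, Fish and Eggs"
    DAIRY = "Dairy"
    UNHEALTHY = "Unhealthy Foods"


#: The five core (non-discretionary) food groups.
FIVE_FOOD_GROUPS: tuple[FoodGroup, ...] = (
    FoodGroup.FRUIT,
    FoodGroup.VEGETABLES,
    FoodGroup.GRAINS,
    FoodGroup.MEAT,
    FoodGroup.DAIRY,
)


class HealthinessTier(str, enum.Enum):
    BEST = "Best Choice"
    LESS_HEALTHY = "Less Healthy Choice"
    UNHEALTHY = "Unhealthy Foods"


#: Serve-factor CSV column per five-food group.
SERVE_COLUMNS: dict[FoodGroup, str] = {
    FoodGroup.FRUIT: "serves_fruit_per_100g",
    FoodGroup.VEGETABLES: "serves_veg_per_100g",
    FoodGroup.GRAINS: "serves_grains_per_100g",
    FoodGroup.MEAT: "serves_meat_per_100g",
    FoodGroup.DAIRY: "serves_dairy_per_100g",
}

REFERENCE_COLUMNS = [
    "food_code",
    "description",
    "energy_density_kj_per_100g",
    *SERVE_COLUMNS.values(),
    "is_discretionary",
    "unhealthy_subgroup",
    "tier",
    "is_alcohol",
]

#: Default unhealthy-food subgroups (Australian Health Survey discretionary
#: classification); replaceable via a scheme JSON document.
DEFAULT_SUBGROUPS: tuple[tuple[str, str], ...] = (
    ("sugar_sweetened_beverages", "Sugar-sweetened beverages"),
    ("cordials_fruit_drinks", "Cordials and fruit drinks"),
    ("confectionery", "Confectionery and chocolate"),
    ("sweet_biscuits", "Sweet biscuits"),
    ("cakes_muffins", "Cakes, muffins and pastries"),
    ("ice_cream_desserts", "Ice cream and dairy desserts"),
    ("savoury_snacks", "Savoury snacks and crisps"),
    ("savoury_pastries", "Savoury pies and pastries"),
    ("takeaway_fried_foods", "Takeaway and fried foods"),
    ("processed_meats", "Processed meats"),
    ("table_sugar", "Table sugar and syrups"),
    ("sweet_spreads", "Jam, honey and sweet spreads"),
    ("sauces_condiments", "Sauces, dressings and condiments"),
)


class SchemeError(ValueError):
    """Raised when a classification scheme document is malformed."""


class ClassificationScheme(BaseModel):
    """The taxonomy reports are built on: groups, tiers, unhealthy subgroups."""

    groups: list[str] = Field(default_factory=lambda: [g.value for g in FoodGroup])
    tiers: list[str] = Field(default_factory=lambda: [t.value for t in HealthinessTier])
    subgroups: dict[str, str] = Field(
        default_factory=lambda: dict(DEFAULT_SUBGROUPS),
        description="subgroup id -> display label",
    )

    @model_validator(mode="after")
    def _check_cardinalities(self) -> "ClassificationScheme":
        if len(set(self.groups)) != len(self.groups):
            raise SchemeError("duplicate group names")
        if len(set(self.tiers)) != len(self.tiers):
            raise SchemeError("duplicate tier names")
        return self

    @classmethod
    def default(cls) -> "ClassificationScheme":
        return cls()

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassificationScheme":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2), encoding="utf-8")


def default_scheme() -> ClassificationScheme:
    """The packaged scheme: 6 groups, 3 tiers, 13 unhealthy subgroups."""
    return ClassificationScheme.default()


class FoodReferenceRecord(BaseModel):
    """One food code with its energy density, serve factors and flags."""

    food_code: str
    description: str = ""
    energy_density: float = Field(ge=0.0, description="kJ per 100 g (100 mL for beverages)")
    serve_factors: dict[FoodGroup, float] = Field(
        default_factory=dict, description="five-food-group serves per 100 g"
    )
    is_discretionary: bool = False
    unhealthy_subgroup: Optional[str] = None
    tier: HealthinessTier
    is_alcohol: bool = False

    @field_validator("serve_factors")
    @classmethod
    def _non_negative(cls, v: dict[FoodGroup, float]) -> dict[FoodGroup, float]:
        for g, f in v.items():
            if g is FoodGroup.UNHEALTHY:
                raise ValueError("serve factors are stored for the five food groups only")
            if f < 0:
                raise ValueError(f"negative serve factor for {g.value}")
        # canonical form: every five-food group present (zero-filled)
        return {g: float(v.get(g, 0.0)) for g in FIVE_FOOD_GROUPS}

    @model_validator(mode="after")
    def _consistency(self) -> "FoodReferenceRecord":
        if self.is_discretionary and any(f > 0 for f in self.serve_factors.values()):
            # Named rule: discretionary-exclusion. Discretionary foods never
            # contribute serves to the five food groups.
            raise ValueError(
                "discretionary-exclusion: discretionary food carries a nonzero "
                "five-food-group serve factor"
            )
        if self.is_discretionary != (self.tier is HealthinessTier.UNHEALTHY):
            raise ValueError("tier 'Unhealthy Foods' must coincide with the discretionary flag")
        if self.unhealthy_subgroup is not None and not self.is_discretionary:
            raise ValueError("unhealthy subgroup set on a non-discretionary food")
        return self

    def serve_factor(self, group: FoodGroup) -> float:
        return self.serve_factors.get(group, 0.0)


@dataclass
class LoadReport:
    """Row-level outcome of loading a reference table."""

    n_loaded: int = 0
    n_rejected: int = 0
    diagnostics: list[str] = field(default_factory=list)


class FoodReference:
    """Validated collection of food reference records, keyed by food code."""

    def __init__(self, records: list[FoodReferenceRecord], scheme: ClassificationScheme | None = None):
        self.scheme = scheme or default_scheme()
        self._records: dict[str, FoodReferenceRecord] = {}
        for rec in records:
            if rec.food_code in self._records:
                raise ValueError(f"duplicate food_code {rec.food_code!r}")
            if rec.unhealthy_subgroup is not None and rec.unhealthy_subgroup not in self.scheme.subgroups:
                raise ValueError(
                    f"unknown unhealthy subgroup {rec.unhealthy_subgroup!r} "
                    f"for food {rec.food_code!r}"
                )
            self._records[rec.food_code] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, food_code: str) -> bool:
        return food_code in self._records

    def __getitem__(self, food_code: str) -> FoodReferenceRecord:
        return self._records[food_code]

    def records(self) -> list[FoodReferenceRecord]:
        return list(self._records.values())

    def to_frame(self) -> pd.DataFrame:
        """Reference table as a DataFrame in the on-disk column layout."""
        rows = []
        for rec in self._records.values():
            row = {
                "food_code": rec.food_code,
                "description": rec.description,
                "energy_density_kj_per_100g": rec.energy_density,
                "is_discretionary": rec.is_discretionary,
                "unhealthy_subgroup": rec.unhealthy_subgroup or "",
                "tier": rec.tier.value,
                "is_alcohol": rec.is_alcohol,
            }
            for g, col in SERVE_COLUMNS.items():
                row[col] = rec.serve_factor(g)
            rows.append(row)
        return pd.DataFrame(rows, columns=REFERENCE_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _record_from_row(row: pd.Series) -> FoodReferenceRecord:
    sub = row["unhealthy_subgroup"]
    if pd.isna(sub) or str(sub).strip() == "":
        sub = None
    return FoodReferenceRecord(
        food_code=str(row["food_code"]),
        description="" if pd.isna(row["description"]) else str(row["description"]),
        energy_density=float(row["energy_density_kj_per_100g"]),
        serve_factors={g: float(row[col]) for g, col in SERVE_COLUMNS.items()},
        is_discretionary=_parse_bool(row["is_discretionary"]),
        unhealthy_subgroup=sub,
        tier=HealthinessTier(str(row["tier"]).strip()),
        is_alcohol=_parse_bool(row["is_alcohol"]),
    )


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f", ""}:
        return False
    raise ValueError(f"cannot parse boolean {v!r}")


def load_reference_table(
    path: str | Path, scheme: ClassificationScheme | None = None
) -> tuple[FoodReference, LoadReport]:
    """Load and validate a food reference CSV.

    Rows violating record invariants (negative energy, discretionary-exclusion,
    unknown subgroup, ...) are rejected individually with row-level diagnostics;
    a missing mandatory column or a duplicate food code aborts the load.
    """
    scheme = scheme or default_scheme()
    df = pd.read_csv(path, dtype={"food_code": str})
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemeError(f"reference table missing mandatory columns: {missing}")
    dupes = df["food_code"][df["food_code"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate food_code values: {dupes}")

    report = LoadReport()
    records: list[FoodReferenceRecord] = []
    for i, row in df.iterrows():
        try:
            rec = _record_from_row(row)
            if rec.unhealthy_subgroup is not None and rec.unhealthy_subgroup not in scheme.subgroups:
                raise ValueError(f"unknown unhealthy subgroup {rec.unhealthy_subgroup!r}")
        except (ValueError, TypeError) as exc:
            report.n_rejected += 1
            report.diagnostics.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
            continue
        records.append(rec)
        report.n_loaded += 1
    return FoodReference(records, scheme), report


@dataclass(frozen=True)
class Classification:
    group: Optional[FoodGroup]
    tier: HealthinessTier
    subgroup: Optional[str]

    @property
    def unclassifiable(self) -> bool:
        return self.group is None


def classify_food(record: FoodReferenceRecord) -> Classification:
    """Assign a food its primary group, tier and (if discretionary) subgroup.

    Discretionary foods map to Unhealthy Foods.  A five-food-group food maps
    to the group with the largest serve factor; ties break alphabetically on
    the group name.  A non-discretionary food with all-zero serve factors is
    unclassifiable (group None) — reported, never fatal.
    """
    if record.is_discretionary:
        return Classification(FoodGroup.UNHEALTHY, HealthinessTier.UNHEALTHY, record.unhealthy_subgroup)
    positive = {g: f for g, f in record.serve_factors.items() if f > 0}
    if not positive:
        return Classification(None, record.tier, None)
    top = max(positive.values())
    candidates = sorted((g for g, f in positive.items() if f == top), key=lambda g: g.value)
    return Classification(candidates[0], record.tier, None)
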