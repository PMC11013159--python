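"""Population-weighted dietary-guideline targets and the reference energy.

Guideline recommendations are given per demographic stratum (age band x sex)
in serves/person/day.  The store-level target for a food group is the
population-proportion-weighted mean of the per-stratum recommendations,
rounded to the nearest 0.5 serves (midpoints round up).  For Unhealthy Foods
the per-stratum figure supplied must be the upper limit of the discretionary
recommendation, and the target direction is at-most rather than at-least.
The reference daily energy requirement is the weighted mean of per-stratum
estimated energy requirements (EER), rounded to the nearest 100 kJ so the
canonical 8.9 MJ/person/day is representable exactly.

The packaged default targets are the published population-weighted values for
the very-remote Australian Indigenous population (2011 Census weighting);
the weighting machinery here lets alternative demographics be substituted.
"""

from __future__ import annotations

import enum
import json
import math
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .indicators import GROUP_KEYS
from .reference_data import FIVE_FOOD_GROUPS, FoodGroup, SchemeError

STRATA_COLUMNS = [
    "stratum_id", "weight", "serves_fruit", "serves_veg", "serves_grains",
    "serves_meat", "serves_dairy", "serves_discretionary_upper", "eer_kj",
]

_STRATA_GROUP_COLUMNS: dict[FoodGroup, str] = {
    FoodGroup.FRUIT: "serves_fruit",
    FoodGroup.VEGETABLES: "serves_veg",
    FoodGroup.GRAINS: "serves_grains",
    FoodGroup.MEAT: "serves_meat",
    FoodGroup.DAIRY: "serves_dairy",
    FoodGroup.UNHEALTHY: "serves_discretionary_upper",
}

_WEIGHT_TOL = 1e-9


class Direction(str, enum.Enum):
    AT_LEAST = "at_least"
    AT_MOST = "at_most"


class Target(BaseModel):
    value: float = Field(ge=0, description="serves/person/day")
    direction: Direction


class TargetSet(BaseModel):
    """Per-group guideline targets plus the reference daily energy."""

    targets: dict[str, Target]
    reference_energy: float = Field(gt=0, description="kJ/person/day")

    @model_validator(mode="after")
    def _directions(self) -> "TargetSet":
        for g in FIVE_FOOD_GROUPS:
            t = self.targets.get(GROUP_KEYS[g])
            if t is not None and t.direction is not Direction.AT_LEAST:
                raise ValueError(f"{g.value} target must be at-least")
        t = self.targets.get(GROUP_KEYS[FoodGroup.UNHEALTHY])
        if t is not None and t.direction is not Direction.AT_MOST:
            raise ValueError("Unhealthy Foods target must be at-most")
        return self

    def target_for(self, indicator_key: str) -> Target | None:
        return self.targets.get(indicator_key)

    @classmethod
    def from_json(cls, path: str | Path) -> "TargetSet":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2), encoding="utf-8")


def default_targets() -> TargetSet:
    """The packaged population-weighted guideline targets.

    Fruit >=2, Vegetables >=5, Breads and Cereals >=5.5, Meat/Fish/Eggs >=2.5,
    Dairy >=2.5 serves/person/day; Unhealthy Foods <=2.5 serves/person/day;
    reference energy 8 900 kJ/person/day.
    """
    at_least = Direction.AT_LEAST
    return TargetSet(
        targets={
            GROUP_KEYS[FoodGroup.FRUIT]: Target(value=2.0, direction=at_least),
            GROUP_KEYS[FoodGroup.VEGETABLES]: Target(value=5.0, direction=at_least),
            GROUP_KEYS[FoodGroup.GRAINS]: Target(value=5.5, direction=at_least),
            GROUP_KEYS[FoodGroup.MEAT]: Target(value=2.5, direction=at_least),
            GROUP_KEYS[FoodGroup.DAIRY]: Target(value=2.5, direction=at_least),
            GROUP_KEYS[FoodGroup.UNHEALTHY]: Target(value=2.5, direction=Direction.AT_MOST),
        },
        reference_energy=8900.0,
    )


def round_to_half(x: float) -> float:
    """Round serves to the nearest 0.5; midpoints round up (2.25 -> 2.5)."""
    if x < 0:
        raise ValueError("serves cannot be negative")
    return math.floor(2.0 * x + 0.5) / 2.0


def load_strata(path: str | Path) -> pd.DataFrame:
    """Read and validate a demographic strata table."""
    df = pd.read_csv(path, dtype={"stratum_id": str})
    missing = [c for c in STRATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemeError(f"strata table missing mandatory columns: {missing}")
    _validate_strata(df)
    return df[STRATA_COLUMNS]


def _validate_strata(strata: pd.DataFrame) -> None:
    total = float(strata["weight"].sum())
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-6):
        raise ValueError(f"stratum weights sum to {total}, expected 1")
    for col in _STRATA_GROUP_COLUMNS.values():
        if (strata[col] < 0).any():
            raise ValueError(f"negative recommendation in column {col}")
    if (strata["eer_kj"] <= 0).any():
        raise ValueError("non-positive EER")


def weighted_target(strata: pd.DataFrame, group: FoodGroup, rounded: bool = True) -> float:
    """Population-weighted mean recommendation for a food group.

    For Unhealthy Foods the strata column must hold the upper limit of the
    discretionary recommendation.  Result is rounded to the nearest 0.5 serves
    unless ``rounded=False``.
    """
    _validate_strata(strata)
    col = _STRATA_GROUP_COLUMNS[group]
    raw = float((strata["weight"] * strata[col]).sum())
    return round_to_half(raw) if rounded else raw


def weighted_eer(strata: pd.DataFrame, rounded: bool = True) -> float:
    """Population-weighted mean estimated energy requirement, kJ/person/day.

    Rounded to the nearest 100 kJ by default.
    """
    _validate_strata(strata)
    raw = float((strata["weight"] * strata["eer_kj"]).sum())
    return round(raw / 100.0) * 100.0 if rounded else raw


def targets_from_strata(strata: pd.DataFrame) -> TargetSet:
    """Derive a full TargetSet (all six groups + reference energy) from strata."""
    targets = {}
    for g in FIVE_FOOD_GROUPS:
        targets[GROUP_KEYS[g]] = Target(value=weighted_target(strata, g), direction=Direction.AT_LEAST)
    targets[GROUP_KEYS[FoodGroup.UNHEALTHY]] = Target(
        value=weighted_target(strata, FoodGroup.UNHEALTHY), direction=Direction.AT_MOST
    )
    return TargetSet(targets=targets, reference_energy=weighted_eer(strata))
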