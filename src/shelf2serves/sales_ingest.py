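"""Read and validate weekly point-of-sale data and link it to the food reference.

Sales arrive as weekly per-product rows (store, week start, product, units,
dollars).  A product catalogue maps product ids to a pack size and a food
reference code; products without a food code (soap, batteries) are non-food.
Linking converts each sale to grams, kilojoules and per-group serves using the
food reference.  Alcohol-flagged foods are removed wholesale; unlinked and
excluded rows are tallied in a linkage report rather than raised.

Beverages are handled on a per-100 mL basis with millilitres stored in the
grams fields (density 1.0 assumed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference_data import FIVE_FOOD_GROUPS, FoodReference, SchemeError

SALES_COLUMNS = ["store_id", "week_start", "product_id", "units_sold", "dollar_value"]
CATALOG_COLUMNS = ["product_id", "description", "pack_size_g", "food_code"]

#: serve columns carried on quantified sales, one per five-food group
QUANT_SERVE_COLUMNS = {g: f"serves_{g.name.lower()}" for g in FIVE_FOOD_GROUPS}


@dataclass
class IngestReport:
    """Row-level outcome of reading a sales file."""

    n_rows: int = 0
    n_valid: int = 0
    n_quarantined: int = 0  # negative quantities (refunds/returns)
    n_malformed: int = 0
    n_merged_duplicates: int = 0
    diagnostics: list[str] = field(default_factory=list)
    quarantined: pd.DataFrame | None = None


def read_sales(path: str | Path) -> tuple[pd.DataFrame, IngestReport]:
    """Read a weekly sales CSV into validated records.

    Malformed rows (unparseable dates or numbers) are rejected with row-level
    diagnostics.  Rows with negative units or dollars are quarantined, not
    counted.  Duplicate (store, week, product) rows are summed with a warning.
    """
    df = pd.read_csv(path, dtype={"store_id": str, "product_id": str})
    missing = [c for c in SALES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemeError(f"sales file missing mandatory columns: {missing}")

    report = IngestReport(n_rows=len(df))
    dates = pd.to_datetime(df["week_start"], format="%Y-%m-%d", errors="coerce")
    units = pd.to_numeric(df["units_sold"], errors="coerce")
    dollars = pd.to_numeric(df["dollar_value"], errors="coerce")

    malformed = dates.isna() | units.isna() | dollars.isna()
    for i in df.index[malformed]:
        report.diagnostics.append(f"row {i + 2}: unparseable date or number")
    report.n_malformed = int(malformed.sum())

    clean = df.loc[~malformed].copy()
    clean["week_start"] = dates[~malformed].dt.date
    clean["units_sold"] = units[~malformed].astype(float)
    clean["dollar_value"] = dollars[~malformed].astype(float)

    negative = (clean["units_sold"] < 0) | (clean["dollar_value"] < 0)
    report.n_quarantined = int(negative.sum())
    report.quarantined = clean.loc[negative, SALES_COLUMNS].reset_index(drop=True)
    for i in clean.index[negative]:
        report.diagnostics.append(f"row {i + 2}: negative quantity quarantined")
    clean = clean.loc[~negative]

    keys = ["store_id", "week_start", "product_id"]
    n_dup = int(clean.duplicated(keys).sum())
    if n_dup:
        report.n_merged_duplicates = n_dup
        report.diagnostics.append(f"merged {n_dup} duplicate (store, week, product) rows by summing")
        clean = clean.groupby(keys, as_index=False)[["units_sold", "dollar_value"]].sum()
    report.n_valid = len(clean)
    return clean[SALES_COLUMNS].reset_index(drop=True), report


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read the product catalogue (product id -> pack size, food code)."""
    df = pd.read_csv(path, dtype={"product_id": str, "food_code": str})
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemeError(f"catalogue missing mandatory columns: {missing}")
    if df["product_id"].duplicated().any():
        raise ValueError("duplicate product_id in catalogue")
    food = df["food_code"].notna() & (df["food_code"].astype(str).str.strip() != "")
    bad = food & ~(pd.to_numeric(df["pack_size_g"], errors="coerce") > 0)
    if bad.any():
        raise ValueError(f"catalogue rows with food_code but non-positive pack size: {list(df.index[bad])}")
    df = df.copy()
    df.loc[~food, "food_code"] = None
    return df[CATALOG_COLUMNS]


@dataclass
class LinkageReport:
    """Accounting of how input sales rows were disposed of during linkage."""

    n_input: int = 0
    n_linked: int = 0
    n_unlinked_product: int = 0  # product_id absent from the catalogue
    n_nonfood: int = 0  # catalogued but no food code
    n_alcohol_excluded: int = 0
    n_unknown_food_code: int = 0  # food code absent from the reference
    alcohol_energy_kj: float = 0.0
    unlinked_product_ids: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return self.n_unlinked_product + self.n_nonfood + self.n_alcohol_excluded + self.n_unknown_food_code


def link_and_quantify(
    sales: pd.DataFrame,
    catalog: pd.DataFrame,
    reference: FoodReference,
    net_refunds: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, LinkageReport]:
    """Convert sales rows to grams, kilojoules and per-group serves.

    grams = units x pack_size; energy = grams x energy_density / 100;
    five-food-group serves = grams x serve_factor / 100 (zero for
    discretionary foods by construction of the reference).  Alcohol-flagged
    foods, non-food products and unlinked product ids are excluded and counted
    in the linkage report.  ``net_refunds``, if given, is a quarantined-refund
    frame whose (negative) quantities are subtracted before quantification.
    """
    report = LinkageReport(n_input=len(sales))
    if net_refunds is not None and len(net_refunds):
        sales = pd.concat([sales, net_refunds], ignore_index=True)
        keys = ["store_id", "week_start", "product_id"]
        sales = sales.groupby(keys, as_index=False)[["units_sold", "dollar_value"]].sum()
        sales = sales.loc[sales["units_sold"] > 0]

    cat = catalog.set_index("product_id")
    rows = []
    for _, sale in sales.iterrows():
        pid = sale["product_id"]
        if pid not in cat.index:
            report.n_unlinked_product += 1
            if pid not in report.unlinked_product_ids:
                report.unlinked_product_ids.append(pid)
            continue
        entry = cat.loc[pid]
        code = entry["food_code"]
        if code is None or (isinstance(code, float) and np.isnan(code)):
            report.n_nonfood += 1
            continue
        if code not in reference:
            report.n_unknown_food_code += 1
            continue
        rec = reference[code]
        grams = float(sale["units_sold"]) * float(entry["pack_size_g"])
        energy = grams * rec.energy_density / 100.0
        if rec.is_alcohol:
            report.n_alcohol_excluded += 1
            report.alcohol_energy_kj += energy
            continue
        row = {
            "store_id": sale["store_id"],
            "week_start": sale["week_start"],
            "food_code": code,
            "grams_sold": grams,
            "energy_kj": energy,
            "dollars": float(sale["dollar_value"]),
            "is_discretionary": rec.is_discretionary,
            "unhealthy_subgroup": rec.unhealthy_subgroup,
            "tier": rec.tier.value,
        }
        for g, col in QUANT_SERVE_COLUMNS.items():
            row[col] = grams * rec.serve_factor(g) / 100.0
        rows.append(row)
        report.n_linked += 1

    columns = [
        "store_id", "week_start", "food_code", "grams_sold", "energy_kj", "dollars",
        "is_discretionary", "unhealthy_subgroup", "tier", *QUANT_SERVE_COLUMNS.values(),
    ]
    quantified = pd.DataFrame(rows, columns=columns)
    return quantified, report
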