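"""Indicator arithmetic: serves, energy normalisation, coverage, shares."""

import math

import numpy as np
import pandas as pd
import pytest

from shelf2serves.indicators import (
    compute_indicator_sets,
    discretionary_coverage,
    dollar_share_by_group,
    indicator_table,
    normalize_to_person_day,
    pivot_indicators,
    read_indicators,
    serves_by_group,
    total_energy,
    write_indicators,
)
from shelf2serves.sales_ingest import link_and_quantify

from conftest import oracle_indicators

COLS = ["store_id", "week_start", "product_id", "units_sold", "dollar_value"]


def _basket(rows) -> pd.DataFrame:
    return pd.DataFrame(
        [("s1", pd.Timestamp("2024-01-01").date(), pid, units, dollars) for pid, units, dollars in rows],
        columns=COLS,
    )


def _quantify(rows, reference, catalog):
    q, _ = link_and_quantify(_basket(rows), catalog, reference)
    return q


def test_total_energy_additive(reference, catalog):
    # 1 kg apples (250 kJ/100 g) + 0.7 kg wholemeal bread (980 kJ/100 g)
    q = _quantify([("P_F001", 1.0, 4.0), ("P_G001", 1.0, 3.0)], reference, catalog)
    assert total_energy(q) == pytest.approx(2500.0 + 6860.0)


def test_total_energy_empty_is_zero(reference, catalog):
    q = _quantify([], reference, catalog)
    assert total_energy(q) == 0.0


def test_unclassifiable_energy_excluded_from_denominator(reference, catalog):
    with_tea = _quantify([("P_F001", 1.0, 4.0), ("P_T001", 5.0, 10.0)], reference, catalog)
    without = _quantify([("P_F001", 1.0, 4.0)], reference, catalog)
    assert total_energy(with_tea) == pytest.approx(total_energy(without))


def test_fruit_serves_from_grams(reference, catalog):
    """300 g of fresh apple at 0.667 serves/100 g is ~2 fruit serves."""
    q = _quantify([("P_F001", 0.3, 1.5)], reference, catalog)  # 0.3 x 1 kg bag
    raw = serves_by_group(q)
    assert raw["fruit"] == pytest.approx(2.0, rel=1e-2)


def test_unhealthy_serves_are_energy_defined(reference, catalog):
    """750 mL of cola at 180 kJ/100 mL: 1350 kJ -> 1350/600 = 2.25 serves."""
    q = _quantify([("P_U001", 0.6, 3.0)], reference, catalog)  # 0.6 x 1.25 L
    raw = serves_by_group(q)
    assert raw["unhealthy_foods"] == pytest.approx(1350.0 / 600.0)
    assert raw["sub_sugar_sweetened_beverages"] == pytest.approx(2.25)


def test_discretionary_contributes_no_five_group_serves(reference, catalog):
    """Hot chips are potato, but discretionary foods never count as vegetables."""
    q = _quantify([("P_U009", 10.0, 40.0)], reference, catalog)
    raw = serves_by_group(q)
    assert raw["vegetables"] == 0.0
    assert raw["unhealthy_foods"] > 0


@pytest.mark.parametrize(
    "serves,energy,expected",
    [(4.0, 17800.0, 2.0), (2.0, 8900.0, 2.0), (3.0, 26700.0, 1.0)],
)
def test_normalization_to_person_day(serves, energy, expected):
    assert normalize_to_person_day(serves, energy) == pytest.approx(expected)


def test_zero_energy_gives_undefined_not_zerodivision():
    assert math.isnan(normalize_to_person_day(2.0, 0.0))


def test_coverage_direct_ratio(reference, catalog):
    # cola (subgrouped) and instant noodles (no subgroup)
    q = _quantify([("P_U001", 1.0, 4.0), ("P_U014", 1.0, 3.0)], reference, catalog)
    cola_kj = 1250 * 180 / 100.0
    noodle_kj = 425 * 1900 / 100.0
    frac, defined = discretionary_coverage(q)
    assert defined
    assert frac == pytest.approx(cola_kj / (cola_kj + noodle_kj))


def test_coverage_fully_subgrouped_is_one(reference, catalog):
    q = _quantify([("P_U001", 1.0, 4.0), ("P_U003", 2.0, 8.0)], reference, catalog)
    frac, defined = discretionary_coverage(q)
    assert defined and frac == pytest.approx(1.0)


def test_coverage_undefined_without_discretionary(reference, catalog):
    q = _quantify([("P_F001", 1.0, 4.0)], reference, catalog)
    frac, defined = discretionary_coverage(q)
    assert not defined and math.isnan(frac)


def test_dollar_shares_sum_to_one(reference, catalog):
    q = _quantify([("P_F001", 2.0, 30.0), ("P_U001", 4.0, 70.0)], reference, catalog)
    shares = dollar_share_by_group(q, reference)
    assert shares["fruit"] == pytest.approx(0.30)
    assert shares["unhealthy_foods"] == pytest.approx(0.70)
    assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
def test_scale_invariance(reference, catalog, k):
    """Doubling every sale changes no serves/person/day value."""
    rows = [("P_F001", 1.0, 4.0), ("P_G001", 2.0, 6.0), ("P_U001", 3.0, 9.0), ("P_D001", 1.5, 3.0)]
    base = compute_indicator_sets(_quantify(rows, reference, catalog))[0]
    scaled_rows = [(p, u * k, d * k) for p, u, d in rows]
    scaled = compute_indicator_sets(_quantify(scaled_rows, reference, catalog))[0]
    for key, v in base.serves_per_person_day.items():
        assert scaled.serves_per_person_day[key] == pytest.approx(v, rel=1e-9, abs=1e-12)


def test_oracle_equivalence_random_baskets(reference, catalog):
    """Pipeline output matches an explicit per-record loop on small baskets."""
    rng = np.random.default_rng(20240101)
    products = [f"P_{c}" for c in ["F001", "F004", "V001", "G001", "G002", "M003",
                                   "D001", "U001", "U007", "U014", "A001", "T001"]] + ["N001"]
    for _ in range(30):
        n = rng.integers(1, 11)
        rows = [
            (products[rng.integers(0, len(products))], float(rng.uniform(0.1, 20)), float(rng.uniform(1, 50)))
            for _ in range(n)
        ]
        sales = _basket(rows)
        q, _ = link_and_quantify(sales, catalog, reference)
        sets = compute_indicator_sets(q)
        expected = oracle_indicators(sales, catalog, reference)
        assert len(sets) == len(expected)
        for s in sets:
            exp = expected[(s.store_id, s.period)]
            assert s.total_energy_kj == pytest.approx(exp["total_energy"], rel=1e-9)
            for key, v in s.serves_per_person_day.items():
                e = exp.get(key, 0.0 if s.total_energy_kj == 0 else None)
                if e is None:
                    e = 0.0
                if math.isnan(v):
                    assert s.no_sales
                else:
                    assert v == pytest.approx(e, rel=1e-9, abs=1e-12), key


def test_subgroups_never_exceed_unhealthy_group(reference, catalog):
    rows = [("P_U001", 2.0, 5.0), ("P_U014", 1.0, 3.0), ("P_F001", 1.0, 4.0)]
    s = compute_indicator_sets(_quantify(rows, reference, catalog))[0]
    sub_total = sum(v for k, v in s.serves_per_person_day.items() if k.startswith("sub_"))
    assert sub_total <= s.serves_per_person_day["unhealthy_foods"] + 1e-12


def test_tidy_output_round_trips(tmp_path, reference, catalog):
    rows = [("P_F001", 1.0, 4.0), ("P_U001", 2.0, 5.0)]
    sets = compute_indicator_sets(_quantify(rows, reference, catalog))
    csv = tmp_path / "ind.csv"
    write_indicators(sets, csv, tmp_path / "ind.json")
    back = read_indicators(csv)
    wide_orig = pivot_indicators(indicator_table(sets))
    wide_back = pivot_indicators(back)
    pd.testing.assert_frame_equal(wide_orig, wide_back, check_exact=False, rtol=1e-10)
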