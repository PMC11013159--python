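"""Sales reading, validation, quantification and linkage accounting."""

import pandas as pd
import pytest

from shelf2serves.sales_ingest import link_and_quantify, read_catalog, read_sales

SALES_HEADER = "store_id,week_start,product_id,units_sold,dollar_value\n"


def _sales(tmp_path, body: str):
    p = tmp_path / "sales.csv"
    p.write_text(SALES_HEADER + body)
    return p


def test_well_formed_rows_all_read(tmp_path):
    body = "".join(f"s1,2024-01-01,P{i},{i + 1},{i * 2.5}\n" for i in range(10))
    df, report = read_sales(_sales(tmp_path, body))
    assert len(df) == 10 and report.n_valid == 10 and report.n_malformed == 0


def test_duplicate_rows_summed_with_warning(tmp_path):
    df, report = read_sales(_sales(tmp_path, "s1,2024-01-01,P1,3,6.0\ns1,2024-01-01,P1,2,4.0\n"))
    assert len(df) == 1
    assert df["units_sold"].iloc[0] == pytest.approx(5.0)
    assert df["dollar_value"].iloc[0] == pytest.approx(10.0)
    assert report.n_merged_duplicates == 1 and report.diagnostics


def test_negative_units_quarantined(tmp_path):
    df, report = read_sales(_sales(tmp_path, "s1,2024-01-01,P1,-1,0\ns1,2024-01-01,P2,2,4\n"))
    assert len(df) == 1 and report.n_quarantined == 1
    assert len(report.quarantined) == 1


def test_unparseable_date_rejected_with_diagnostic(tmp_path):
    df, report = read_sales(_sales(tmp_path, "s1,notadate,P1,1,1\ns1,2024-01-01,P2,2,4\n"))
    assert len(df) == 1 and report.n_malformed == 1
    assert any("row 2" in d for d in report.diagnostics)


def test_catalog_requires_positive_pack_size_for_food(tmp_path):
    p = tmp_path / "cat.csv"
    p.write_text("product_id,description,pack_size_g,food_code\nP1,Apple bag,0,F001\n")
    with pytest.raises(ValueError, match="pack size"):
        read_catalog(p)


@pytest.fixture
def cola_sale():
    return pd.DataFrame(
        [("s1", pd.Timestamp("2024-01-01").date(), "P_U001", 2.0, 5.0)],
        columns=["store_id", "week_start", "product_id", "units_sold", "dollar_value"],
    )


def test_quantification_grams_and_energy(reference, catalog, cola_sale):
    """2 units x 1.25 L cola at 180 kJ/100 mL -> 2500 g, 4500 kJ."""
    q, report = link_and_quantify(cola_sale, catalog, reference)
    assert report.n_linked == 1
    assert q["grams_sold"].iloc[0] == pytest.approx(2500.0)
    assert q["energy_kj"].iloc[0] == pytest.approx(2500.0 * 180.0 / 100.0)


def test_alcohol_excluded_wholesale(reference, catalog):
    sales = pd.DataFrame(
        [("s1", pd.Timestamp("2024-01-01").date(), "P_A001", 1.0, 6.0)],
        columns=["store_id", "week_start", "product_id", "units_sold", "dollar_value"],
    )
    q, report = link_and_quantify(sales, catalog, reference)
    assert len(q) == 0
    assert report.n_alcohol_excluded == 1
    assert report.alcohol_energy_kj == pytest.approx(375.0 * 150.0 / 100.0)


def test_nonfood_and_unlinked_excluded(reference, catalog):
    sales = pd.DataFrame(
        [
            ("s1", pd.Timestamp("2024-01-01").date(), "N001", 1.0, 2.0),  # soap
            ("s1", pd.Timestamp("2024-01-01").date(), "ZZZZ", 1.0, 2.0),  # unknown product
        ],
        columns=["store_id", "week_start", "product_id", "units_sold", "dollar_value"],
    )
    q, report = link_and_quantify(sales, catalog, reference)
    assert len(q) == 0
    assert report.n_nonfood == 1
    assert report.n_unlinked_product == 1
    assert report.unlinked_product_ids == ["ZZZZ"]


def test_linkage_conservation(reference, catalog):
    """linked + unlinked + non-food + alcohol rows account for every input row."""
    rows = [
        ("s1", pd.Timestamp("2024-01-01").date(), pid, 1.0, 1.0)
        for pid in ["P_F001", "P_U001", "P_A001", "N001", "MISSING", "P_D001"]
    ]
    sales = pd.DataFrame(rows, columns=["store_id", "week_start", "product_id", "units_sold", "dollar_value"])
    q, report = link_and_quantify(sales, catalog, reference)
    assert report.n_linked + report.n_excluded == report.n_input == 6
    assert report.n_linked == len(q) == 3


def test_energy_additivity_over_concatenation(reference, catalog):
    a = pd.DataFrame(
        [("s1", pd.Timestamp("2024-01-01").date(), "P_F001", 3.0, 5.0)],
        columns=["store_id", "week_start", "product_id", "units_sold", "dollar_value"],
    )
    b = pd.DataFrame(
        [("s1", pd.Timestamp("2024-01-08").date(), "P_G001", 2.0, 7.0)],
        columns=["store_id", "week_start", "product_id", "units_sold", "dollar_value"],
    )
    qa, _ = link_and_quantify(a, catalog, reference)
    qb, _ = link_and_quantify(b, catalog, reference)
    qab, _ = link_and_quantify(pd.concat([a, b], ignore_index=True), catalog, reference)
    assert qab["energy_kj"].sum() == pytest.approx(qa["energy_kj"].sum() + qb["energy_kj"].sum())


def test_net_refunds_subtracts_quarantined(tmp_path, reference, catalog):
    body = "s1,2024-01-01,P_F001,5,10\ns1,2024-01-01,P_F001,-2,-4\n"
    df, report = read_sales(_sales(tmp_path, body))
    q_drop, _ = link_and_quantify(df, catalog, reference)
    q_net, _ = link_and_quantify(df, catalog, reference, net_refunds=report.quarantined)
    assert q_drop["grams_sold"].iloc[0] == pytest.approx(5000.0)
    assert q_net["grams_sold"].iloc[0] == pytest.approx(3000.0)
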