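"""Synthetic generator: fixture coverage, determinism, ground-truth recovery."""

import math

import numpy as np
import pytest

from shelf2serves.indicators import compute_indicator_sets, discretionary_coverage
from shelf2serves.reference_data import FoodGroup, HealthinessTier, classify_food
from shelf2serves.sales_ingest import link_and_quantify
from shelf2serves.synthetic import (
    GenerationError,
    ScenarioSpec,
    generate_reference_fixture,
    generate_sales,
    random_scenario,
)


def test_fixture_covers_full_taxonomy(reference, scheme, catalog):
    assert len(reference) >= 40
    groups = {classify_food(r).group for r in reference.records()}
    assert groups >= set(FoodGroup)
    tiers = {r.tier for r in reference.records()}
    assert tiers == set(HealthinessTier)
    subgroups = {r.unhealthy_subgroup for r in reference.records() if r.unhealthy_subgroup}
    assert subgroups == set(scheme.subgroups)
    assert any(r.is_alcohol for r in reference.records())
    assert catalog["food_code"].isna().any() or (catalog["food_code"] == None).any()  # noqa: E711


def test_fixture_edge_classifications(reference):
    juice = classify_food(reference["F004"])
    assert (juice.group, juice.tier) == (FoodGroup.FRUIT, HealthinessTier.LESS_HEALTHY)
    disc = reference["U009"]  # takeaway hot chips
    assert disc.is_discretionary and all(f == 0 for f in disc.serve_factors.values())


def _recover(spec, reference, catalog):
    sales, truth = generate_sales(spec, reference, catalog)
    q, _ = link_and_quantify(sales, catalog, reference)
    sets = compute_indicator_sets(q, period_unit="month")
    return sales, truth, q, sets


def test_noise_free_round_trip_exact(reference, catalog):
    spec = ScenarioSpec(n_stores=1, n_weeks=4, seed=3,
                        target_indicators={"fruit": 2.0})
    _, truth, q, sets = _recover(spec, reference, catalog)
    assert truth["fruit"] == 2.0
    for s in sets:
        for key, expected in truth.items():
            if key in ("weekly_energy_kj", "discretionary_coverage"):
                continue
            got = s.serves_per_person_day[key]
            assert got == pytest.approx(expected, rel=1e-6), key
    cov, defined = discretionary_coverage(q)
    assert defined and cov == pytest.approx(truth["discretionary_coverage"], rel=1e-9)


def test_weekly_energy_matches_budget(reference, catalog):
    spec = ScenarioSpec(n_stores=1, n_weeks=1, seed=0, weekly_energy_kj=17800.0)
    _, truth, q, sets = _recover(spec, reference, catalog)
    assert sets[0].total_energy_kj == pytest.approx(17800.0, rel=1e-9)


def test_same_seed_identical_bytes(tmp_path, reference, catalog):
    spec = ScenarioSpec(n_stores=2, n_weeks=3, seed=42, noise=0.2)
    a, _ = generate_sales(spec, reference, catalog)
    b, _ = generate_sales(spec, reference, catalog)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    a.to_csv(pa, index=False, float_format="%.10g")
    b.to_csv(pb, index=False, float_format="%.10g")
    assert pa.read_bytes() == pb.read_bytes()


def test_weekly_volume_noise_is_indicator_neutral(reference, catalog):
    """Whole-week lognormal scaling cancels in the serves/energy ratio, so
    even noisy streams recover the target within each week's pooled period."""
    spec = ScenarioSpec(n_stores=1, n_weeks=8, seed=5, noise=0.3)
    _, truth, _, sets = _recover(spec, reference, catalog)
    for s in sets:
        assert s.serves_per_person_day["fruit"] == pytest.approx(truth["fruit"], rel=1e-6)


def test_product_jitter_recovers_target_in_expectation(reference, catalog):
    """Per-product jitter perturbs single weeks; the annual mean should land
    within 3 Monte-Carlo standard errors of the requested value."""
    target = 7.0
    spec = ScenarioSpec(n_stores=1, n_weeks=52, seed=9, product_jitter=0.1,
                        target_indicators={"unhealthy_foods": target})
    sales, truth, q, _ = _recover(spec, reference, catalog)
    monthly = compute_indicator_sets(q, period_unit="month")
    vals = np.array([s.serves_per_person_day["unhealthy_foods"] for s in monthly])
    se = vals.std(ddof=1) / math.sqrt(len(vals))
    assert abs(vals.mean() - target) <= 3 * max(se, 1e-6)


def test_unachievable_scenario_names_the_gap(reference, catalog):
    spec = ScenarioSpec(target_indicators={"unhealthy_foods": 20.0})
    with pytest.raises(GenerationError, match="unhealthy_foods"):
        generate_sales(spec, reference, catalog)
    spec2 = ScenarioSpec(target_indicators={"unknown_key": 1.0})
    with pytest.raises(GenerationError, match="unsupported"):
        generate_sales(spec2, reference, catalog)


def test_subgroup_targets_honoured(reference, catalog):
    spec = ScenarioSpec(n_stores=1, n_weeks=2, seed=1,
                        target_indicators={"sub_sugar_sweetened_beverages": 2.0})
    _, truth, _, sets = _recover(spec, reference, catalog)
    assert truth["sub_sugar_sweetened_beverages"] == 2.0
    for s in sets:
        assert s.serves_per_person_day["sub_sugar_sweetened_beverages"] == pytest.approx(2.0, rel=1e-6)


def test_random_scenarios_are_achievable_and_recovered(reference, catalog):
    rng = np.random.default_rng(2024)
    for _ in range(5):
        spec = random_scenario(rng, n_stores=1, n_weeks=2)
        _, truth, _, sets = _recover(spec, reference, catalog)
        for s in sets:
            for key in ("fruit", "vegetables", "breads_cereals", "meat_fish_eggs",
                        "dairy", "unhealthy_foods"):
                assert s.serves_per_person_day[key] == pytest.approx(truth[key], rel=1e-6)
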