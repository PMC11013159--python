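# shelf2serves

Turns weekly store point-of-sale (POS) data into the key dietary indicators of
the Australian Dietary Guidelines and renders customisable store reports.
It is built for the people who run and advise community food stores — store
boards, managers and public-health nutritionists — who receive weekly sales
extracts but need to know *"are we selling a healthier basket than last
quarter, and are we near the guideline targets?"*

## The indicators

Each product sold is linked, via a product catalogue, to a food reference
record carrying an energy density (kJ/100 g), per-100 g serve factors for the
five core food groups (Fruit; Vegetables; Breads and Cereals; Meat, Fish and
Eggs; Dairy), and a discretionary ("Unhealthy Foods") flag with one of 13
unhealthy subgroups. For a store *s* and period *t*, the indicator for food
group *g* is the energy-normalised serves per person per day:

```
I_g(s,t) = ( Σ serves_g sold ) × E_ref / ( Σ kJ sold ),    E_ref = 8 900 kJ/person/day
```

Five-food-group serves come from grams × serve factor over non-discretionary
foods only (the potato in deep-fried hot chips never counts as vegetables);
Unhealthy Foods serves are energy-defined at 600 kJ per discretionary serve.
Alcohol is excluded wholesale. Normalising by energy purchased makes stores
of different sizes and periods of different lengths directly comparable, and
makes every indicator invariant to uniform scaling of the basket.

Indicators are compared with population-weighted guideline targets
(derived from per-stratum recommendations weighted by census population
proportions and rounded to the nearest 0.5 serves):
Fruit ≥ 2, Vegetables ≥ 5, Breads and Cereals ≥ 5.5, Meat/Fish/Eggs ≥ 2.5,
Dairy ≥ 2.5 and Unhealthy Foods ≤ 2.5 serves/person/day.

## Worked example

Real community-store sales are ethically restricted, so the package ships a
synthetic generator that builds a complete input set with known ground truth:

```bash
shelf2serves simulate --seed 7 --out demo
```

```
ground-truth indicators (serves/person/day):
  fruit                            1.0000
  vegetables                       2.5000
  breads_cereals                   4.5000
  meat_fish_eggs                   2.0000
  dairy                            1.5000
  unhealthy_foods                  6.0000
  ...
  discretionary_coverage           0.8770
```

These are the generator's demo conditions: healthy-food sales below the
guideline targets and discretionary sales well above the ≤ 2.5 limit, with
87.7 % of discretionary energy in the 13 named subgroups. Computing the
indicators back from the raw weekly sales:

```bash
shelf2serves compute --sales demo/sales.csv --catalog demo/catalog.csv \
    --reference demo/reference.csv --out demo/ind
# wrote indicators for 3 store(s), 18 store-period(s) to demo/ind
head -3 demo/ind/indicators.csv
# store_id,period,indicator_key,value,unit
# store_01,2024-01,total_energy,31150000.0011,kJ
# store_01,2024-01,fruit,0.999999999991,serves/person/day
```

The pipeline recovers the constructed fruit value of 1.0 serves/person/day to
float precision — a store selling this basket provides half the ≥ 2 serve
fruit target. Reports with speedometer gauges (green on the
target-satisfying side, inverted for the at-most Unhealthy Foods target),
trend charts and comparator overlays:

```bash
shelf2serves report --sales demo/sales.csv --catalog demo/catalog.csv \
    --reference demo/reference.csv \
    --comparators guideline-target,all-store-average --out demo/reports
```

This writes one self-contained HTML report per store (deterministic bytes
unless `--stamp` is given) plus a JSON payload a hosting portal could serve.

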