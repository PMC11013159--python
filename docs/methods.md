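# Methods

## Indicator model

The unit of analysis is a store × period basket assembled from weekly POS
rows (store, week start, product, units, dollars). Each week belongs wholly
to the calendar month or quarter containing its start date — a deterministic
convention chosen over splitting straddling weeks. Quantification is linear:

- grams = units × pack size (beverages are carried per 100 mL with
  millilitres in the grams fields, density 1.0);
- energy = grams × energy density / 100;
- five-food-group serves = grams × per-group serve factor / 100, over
  non-discretionary foods only;
- Unhealthy Foods serves = discretionary energy / 600 kJ.

The reported indicator is `raw serves × E_ref / total energy` with
E_ref = 8 900 kJ/person/day. Both numerator and denominator are sums over
the basket, so the indicator is exactly invariant to uniform scaling of all
quantities, and period aggregates must be recomputed from pooled base records
(a mean of monthly ratios is not the quarterly ratio — the comparator module
enforces this).

### Denominator scope

Alcohol-flagged foods are removed wholesale (availability varies too much
between communities for a comparable indicator), and non-food products have
no nutrient mapping. Both are excluded from numerator *and* denominator.
Energy of classifiable-food-free records (a food with zero serve factors that
is not discretionary, e.g. tea) is likewise excluded from the denominator;
this is this package's documented choice, so that the denominator is exactly
the energy the numerators can draw on.

### Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| reference energy | 8 900 | kJ/person/day | population-weighted average daily energy requirement (configurable; derivable from a strata table) |
| discretionary serve | 600 | kJ/serve | the guidelines' nominal discretionary serve; the unhealthy indicator is energy-based because discretionary foods have no gram-based serve factor |
| week → period rule | week-start month | — | deterministic, no week splitting |

## Classification taxonomy

Six top-level groups (the five core groups + Unhealthy Foods, mutually
exclusive), three healthiness tiers (Best Choice, Less Healthy Choice,
Unhealthy Foods — the third tier coincides with the discretionary flag), and
13 unhealthy subgroups chosen from the Australian Health Survey discretionary
classification as the biggest contributors to discretionary energy. The
subgroup inventory is configuration (a JSON scheme document), not code; the
count and labels can be replaced without touching the pipeline. Extra
optional groups (e.g. bush/traditional foods) can be added to a scheme, but
market sales data cannot observe non-market foods, so none ship populated.

Validation is enforced at the record level: a discretionary food must carry
all-zero five-group serve factors (the "discretionary-exclusion" rule), a
subgroup implies the discretionary flag, and the Unhealthy tier holds exactly
the discretionary foods. Mixed dishes keep per-group serve factors and all
of them contribute to indicators; the single *primary* group used for report
grouping and dollar shares is the group with the largest factor, ties broken
alphabetically. Classification edge cases fixed in the default reference:
100 % fruit juice and dried fruit are Fruit / Less Healthy Choice; high-fibre
white bread sits with regular white bread as a Less Healthy Choice.

## Targets

Per-stratum guideline recommendations (serves/person/day by age band × sex)
are combined as a population-proportion-weighted mean and rounded to the
nearest 0.5 serves, with midpoints rounding up (the rounding rule only
states "nearest 0.5"; half-up is this package's tie-break). For Unhealthy
Foods the supplied per-stratum figure must be the *upper limit* of the
discretionary recommendation and the target direction is at-most; the five
core groups are at-least. EERs average the same way, rounded to 100 kJ so
8.9 MJ is exact. The packaged default TargetSet carries the published
population-weighted values verbatim; re-deriving them from first principles
would require the census strata and per-stratum recommendation tables, which
are inputs here, not package data.

## Synthetic data

The generator stands in for restricted store sales. It works backwards from
requested serves/person/day values: per 8 900 kJ of basket energy, each core
group's serves are split between a low- and a high-energy-per-serve fixture
food, with a single global mixing fraction solving the linear energy-closure
equation so the basket's total energy is exactly consistent with the
requested unhealthy-foods (energy-defined) serves. Discretionary energy is
spread over the 13 subgroup foods up to a coverage share (default 0.877,
the pooled share of discretionary energy the named subgroups represent in
remote-store sales), remainder to a non-subgrouped discretionary food.
Requested targets outside the composable energy range raise a generation
error naming the feasible interval.

Demo conditions (used when a scenario omits values): fruit 1.0,
vegetables 2.5, breads/cereals 4.5, meat/fish/eggs 2.0, dairy 1.5 — below
the guideline targets — and unhealthy foods 6.0 serves/person/day, matching
the observation that discretionary sales run two to three times the ≤ 2.5
recommendation. Weekly store energy defaults to 6.23 MJ×10³ (~100
person-days at 8.9 MJ). Default streams are 3 stores × 26 weeks; tests and
the acceptance script use 1–3 stores and 2–26 weeks, sizes chosen as the
smallest that exercise multi-store, multi-period behaviour.

Noise model: weekly lognormal volume multipliers (mean 1) scale whole store
weeks; because the indicator is a ratio this is indicator-neutral, so
noise-free *and* week-scaled streams reproduce the ground truth exactly. An
optional per-product lognormal jitter creates genuine indicator variability
with the requested values as expectation. What the generator does **not**
emulate: seasonality, promotions and price elasticity, random-weight produce,
assortment churn, and correlated store effects — passing round-trip tests
therefore validates the arithmetic of the pipeline, not the behaviour of real
shoppers.

## Reports

Gauges are half-dials over [0, max(2 × target, observed value)] so the needle
is always on-scale, split at the target: green on the target-satisfying side,
which flips for the at-most Unhealthy Foods target. Target comparison is
boundary-inclusive. Tier colours use the Okabe–Ito colour-blind-safe palette
(green `#009E73`, amber `#E69F00`, red `#D55E00`). Line trend charts are the
default with bar charts as an option. Undefined indicators (no sales in a
period) render as "no data", never as zero. HTML output embeds SVG with a
fixed hash salt and no timestamp metadata, so identical inputs give
byte-identical reports; `--stamp` opts into a visible timestamp.

## Numerical choices and edge cases

- Zero total energy yields NaN indicators flagged `no_sales`; division by
  zero never occurs.
- Negative sales rows (refunds) are quarantined by default; `--net-refunds`
  subtracts them before quantification instead.
- Duplicate (store, week, product) rows are summed with a warning; linkage
  accounting conserves rows (linked + excluded = input).
- Tolerances: round-trip recovery asserted at 1e-6 relative; oracle and
  scale-invariance at 1e-9 relative (pure float-summation error in practice).

## Limitations

- The reference table is a single pre-joined flat extract; building it from
  the national food-composition databases (and matching free-text product
  names to food codes) is out of scope — the mapping is an input.
- Indicators are food-group serves only; no nutrient-level indicators.
- The all-store average includes the focal store and is unweighted by
  default (each store-community counts once); an energy-weighted pooled
  variant is available behind a flag.
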