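# Methods

## Scope and system boundary

`fishflow` models the post-landing fate of harvested finfish reported in
global production statistics. At-sea discards never enter the accounts;
crustaceans and molluscs are excluded. Non-food utilisation (reduction to
fishmeal and fish oil, pet food) is a productive diversion, not a loss;
post-harvest loss means edible biomass that fails to reach consumers.
Biomass counted as post-harvest loss is terminal within the system
boundary — secondary recovery of degraded material is not modelled.

## Flow model

One unit of harvest is partitioned sequentially and exhaustively:
allocation (`a`), survival of post-harvest loss (`b`), edible-portion
yield (`c`), by-product reuse (`d`). Because every stage is a binary split
of the previous stage's output, the four terminal masses
(non-food `M2`, loss `M4`, direct consumption `M_D`, by-products `M_B`)
partition `M_H` exactly; the ledger constructor enforces all partition
identities to 1e-9 relative and the test suite checks conservation on
randomised parameters to 1e-12 relative.

One historical source states the consumed-stage mass as `M3 = b·M2`; that
is inconsistent with the chain's own prose and with the closed form for
`f`, and is treated as a typo for `M3 = b·M1` throughout.

Adoption `x` is a single scalar applied simultaneously to `a`, `b` and `d`
(harmonised adoption). This is a deliberate simplification: real
interventions act on different nodes (cold chain on early spoilage,
handling on transport damage, valorisation on by-product use), so results
are upper bounds under an idealised, globally comparable scenario, not
forecasts. All three transformed rates are affine and non-decreasing in
`x`, hence `f(x)` is non-decreasing — a property test, not an assumption.

Percent reporting uses round-half-even on the percent scale, which
reproduces the published integers 54, 66 and 74. Internally everything is
a fraction in [0, 1]; `%`-suffixed values are normalised at file-reading
time only.

### Parameters

| symbol | meaning | global default |
|---|---|---|
| `a0` | harvest fraction allocated to food use | 0.89 |
| `b0` | food-use fraction surviving post-harvest loss | 0.81 |
| `c` | edible-portion yield (constant in `x`) | 0.65 |
| `d0` | by-product fraction re-utilised as food | 0.30 |
| `lim_a` | max recoverable improvement of allocation | 0.68 |
| `lim_b` | max stabilisable fraction of losses | 0.56 |
| `d_max` | max food-usable by-product fraction | 0.70 |
| `M_H` | annual harvested mass | 185 Mt |

Continental parameter values are not published in the sources the global
defaults come from; the package therefore ships only the global record and
treats regional tables as user input or synthetic fixtures. Regions are
evaluated independently — no cross-region aggregation or re-averaging.

## Synthetic regional tables

The generator emulates the *structure* of a continental parameter table:
one record per region, each field drawn uniformly from a documented
narrative range (distribution-chain losses under 10% in Europe and North
America, 15–30% in South/Southeast Asia, up to 40% in sub-Saharan Africa,
10–30% in Latin America, wide non-food allocation in Oceania). Uniform
sampling is used because the narratives give ranges, never distributions.
Each call uses a single explicit `numpy` RNG stream, so output is a pure
function of (profiles, seed) and files written from equal-seed tables are
byte-identical.

What the fixtures do **not** emulate: correlations between parameters
within a region, within-region heterogeneity (industrial vs artisanal
chains), trade flows, and any claim to be actual continental estimates —
tables carry `provenance="synthetic"` and passing tests on them shows the
pipeline's correctness, not regional realism.

## Nutrition layer

Conversions: 1 portion = 100 g edible mass; muscle protein content 20%;
annual adult protein requirement 17.5 kg (0.83 g·kg⁻¹·day⁻¹ × 58 kg
reference woman × 365); daily protein requirement 48 g. Global population
defaults to 8.0×10⁹ (configurable; the source of the "10% of the
population" figure does not state one).

RDA coverage divides nutrient content per 100 g dry weight of a
herring-backbone pH-shift protein isolate by the daily requirement, with
g/mg/µg conversion. The isolate is an upper envelope: oily pelagics are
richer in long-chain omega-3s and micronutrients than most whitefish.
Total lipids are requirement-referenced to dietary energy, not mass, and
are excluded from coverage.

Requirements printed as rounded absolute values (e.g. protein 48 g/day,
lysine 1.74 g/day) are used by default so published cells reproduce; the
exact per-kg conversion (0.83 × 58 = 48.14 g/day) is available via
`exact_bodyweight=True`. The published table itself mixes conventions:
most cells recompute to the printed integer or within 1% relative, but the
methionine cell prints 295% while 2.6 g / 0.87 g·day⁻¹ = 298.9% under
either requirement convention — a 1.3% gap with no recoverable rounding
rule. The package reports the computed value and documents the mismatch
instead of special-casing it.

Two published quantities are mutually inconsistent: 31 Mt of recovered
fish at 20% protein is 6.2 Mt of protein, while the companion text says
"roughly 2 Mt". The package computes both; only the internally consistent
step (2 Mt ÷ 17.5 kg → 114 million adults) is treated as reproducible.

## Economics layer

`k1` (supply-chain share of market value, range 0.40–0.60) and `k2`
(fixed share of supply-chain cost, range 0.20–0.30) define three named
scenarios: negative (0.40, 0.20), neutral (0.50, 0.25), positive
(0.60, 0.30). The endpoints and midpoint are the only non-arbitrary
reading of the published ranges, which never state the "neutral" values.

The cost saving per marketed tonne is independent of the variable cost:
variable cost scales exactly with throughput (`C = C_f + (f1/f0)·C_v0`),
so only the fixed cost's dilution over the larger marketed mass remains.
The closed form is verified in tests against a constructive oracle that
builds both cost-per-tonne ledgers explicitly.

Market value `V_F` defaults to the internally consistent `P_F·f0·M_H`
(≈0.90 TUSD at the global baseline); the published estimate of 1.25 TUSD
is available as a `published_compat` override and is used when reproducing
published economics. Neither `P_F·M_H` (1.66 TUSD) nor `P_F·f0·M_H`
equals the published figure; its mass basis is not stated and is not
assumed.

Known non-reproducible figure: the published neutral-scenario saving of
374 USD/t (hence 4105 USD/t and, via ÷k1, the 748 USD/t / 8.4% price
reduction) cannot be obtained from any stated (k1, k2, f0, f1)
combination; the midpoint reconstruction gives ≈406 USD/t. The
`reproduce` report marks the row NOT-REPRODUCED. The baseline
4479 USD/t (= k1·P_F) and the 374 → 748 propagation (÷k1, which exactly
reconciles the published pair) are reproduced. Savings exclude capital,
operating and transition costs of the technologies, and any demand or
price-elasticity response.

A claimed utilisation of "over 85%" appears in discussion-level text with
no derivable parameterisation (the modelled maximum at x = 0.8 is 74%);
it is not reproduced.

## Numerical choices

- All comparisons of published integer percentages use the printed
  precision (half a unit) as the floor of any tolerance.
- Ledger identities: constructor tolerance 1e-9 relative (guards against
  corrupted construction), property tests 1e-12 relative (double
  precision on well-posed chains).
- Degenerate inputs: `M_H ≤ 0`, `x ∉ [0,1]`, rates outside [0,1] and
  `d_max < d0` raise `ValueError` naming the offending field and region;
  empty adoption lists are valid for sweeps (empty output) but invalid
  for a pipeline run.
- Negative utilisation deltas (f below baseline) warn rather than raise,
  since downstream cost formulas remain well defined.
- CSV exports write `%.10g`–`%.17g` floats with fixed row ordering (node
  order, then region, then x), so equal inputs give byte-identical files.

## Problem sizes

Everything is closed-form algebra on scalars; the full test suite
(including property tests at 100 hypothesis examples each and a 300-seed
range-membership sweep of the synthetic generator) and the acceptance
script each run in seconds on one CPU.

## Limitations

Deterministic point estimates only — no uncertainty propagation on the
sub-rates; adoption is harmonised rather than node-specific; nutrient
values are a single-species upper envelope with no bioavailability
adjustment; the economics is a fixed-cost-dilution argument, not a market
model. Regional synthetic tables are test fixtures, not data.
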