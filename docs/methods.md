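# Methods

## Emission model

Annual landfill methane is computed by mass balance. For strategy-style
projections the package uses

    CH4 = Σ_x [ MSW_x · MCF · DOC · DOCf · F · 16/12 · (1−R) · (1−OX) ]

where MSW_x is the mass (Gg) deposited in year x, MCF ∈ [0.4, 1.0] adjusts
for site management quality, DOC is the degradable organic carbon fraction,
DOCf the fraction of DOC that decomposes anaerobically, F the methane
volume fraction of landfill gas, 16/12 the carbon→methane stoichiometric
ratio, and R/OX the recovered and cover-oxidized fractions of generated
gas. Although this form carries the IPCC first-order-decay parameter
names, it contains **no decay constant**: waste deposited in year x is
assumed to emit in year x. That instant-release approximation overstates
early emissions and understates the tail for any individual cohort; over a
steadily growing deposition stream the aggregate error is modest, but the
model should not be used for site closure dynamics. Time-lagged kinetics
are deliberately out of scope.

The site-summed TAME form, `Σ_i [MSW_i·FDOC_i·FD_i·MEF_i·CR_i − MR_i]`, is
the same mass balance with an explicit per-site recovery mass MR_i (Gg/yr)
instead of a recovered fraction. MR_i may arithmetically exceed the gross
term; since a landfill cannot emit negative mass, per-site results are
floored at zero (with a logged warning) before summation. MEF has no
tabulated value and is treated as a dimensionless multiplier defaulting to
1.0; CR defaults to the stoichiometric 16/12.

CH4 mass converts to CO2-equivalent by a GWP factor, default 25 (the
waste-sector reporting convention); 28, a more recent 100-year value, is
selectable. The conversion and its inverse are exact reciprocals.

## Baseline trajectory

The national baseline is anchored at four years
(2022: 4317.58, 2030: 5028.02, 2040: 6250.37, 2050: 7769.88 kt CO2e) and
densified by interpolation. The default is geometric (constant annual
growth between anchors), consistent with the compound population/GDP
growth that drives the projection; linear is available. Anchor years pass
through exactly and extrapolation outside the anchor span is refused. A
zero-valued bracket, where a growth rate is undefined, falls back to
linear interpolation.

## Scenario wedges

An intervention is a wedge subtracted from the baseline. Two modes:

- **absolute** — kt CO2e/yr at milestone years, linearly interpolated
  between milestones and held at the last value afterwards;
- **fraction of baseline** — a dimensionless fraction, held constant
  between milestones so the wedge scales with the growing baseline.

The default ledger encodes the mid-term projects fractionally
(sanitary landfills 0.05, transfer stations 0.01, GPS routing 0.005,
national center 0.01, Husainiyat biogas 0.01 — together 8.5% of baseline)
because their published 2030 and 2040 milestone reductions are exactly
those fractions of the respective baseline anchors. The short-term phase
is one combined absolute wedge of 603.37 kt CO2e/yr at 2030: the published
individual project values sum to 607.4, but the published net
(5028.02 → 4424.65, a 12% reduction) fixes the portfolio total at 603.37,
which is taken as authoritative; the component values are kept as an
informational constant. The long-term phase follows the activity ledger's
2050 values (172.56 and 862.81 kt); the narrative's circular-economy
figures (3,267 and 7,753 kt) exceed the entire baseline and are treated
as erroneous.

Net emissions are floored at zero. Whenever the floor is idle,
baseline − net equals the sum of per-wedge reductions to 1e−9 relative
(property-tested), and the sum is order-independent.

The activity-reduction ledger stores all fourteen entries as published.
One short-term item ("Biogas from Salt Treatment Plant", 19.87 kt) is
listed but excluded from its phase subtotal in the source; the
`counted_in_subtotal` flag reproduces that. The mid-term components sum
to 1489.95 while the source prints 1489.94 (source-side rounding); both
numbers are carried, and the grand total 4335.39 is defined as the sum of
the three printed subtotals.

Strategy comparison takes the five published emission trajectories
(tons CH4/yr, 2025–2050) as given — the diversion parameters behind them
are not published, so re-deriving them is a non-goal — and computes each
strategy's percent reduction against the baseline at a chosen year.

## Health burden

The pathway is methane → tropospheric ozone → respiratory mortality and
morbidity, collapsed to linear factors (deaths/yr and asthma visits/yr
per Gg CH4/yr). Two parameterizations:

- **calibrated** (default): factors are ratios of the published 2022
  anchor row — 245/173 ≈ 1.416 deaths/Gg and 744/173 ≈ 4.301 visits/Gg.
  This reproduces the published burden table to within ±1 death at the
  interior years (the table's own rounding).
- **UNEP benchmark**: 1,400 deaths per Mt CH4 (1.4/Gg), which
  under-predicts the anchor row by about 1%; it carries no asthma factor.

No independent asthma factor exists at this scale; the calibrated value is
a declared modelling choice. The ozone relative risk (1.04) is stored and
reported but not consumed: an attributable-fraction pathway would require
baseline respiratory mortality that is not part of the bundled data.
Display rounding is to the nearest integer.

## Valuation

A VSL is willingness-to-pay for a small mortality-risk reduction divided
by that reduction ($300 for 1-in-10,000 → $3M). Transfers across income
levels use `VSL_t = VSL_r · (income_t/income_r)^elasticity`, elasticity
0.85 by default. The Jordan default is $1.3M (2022), the meta-analytic
worldwide average. The published $7.2M → $1.16M transfer omits its
reference income; `implied_income_ratio` computes the ratio it must have
assumed (≈0.117) as a diagnostic rather than asserting it. Mortality cost
is deaths × VSL at a constant VSL; growing the VSL with projected income
is possible via the transfer but off by default. The published
$1.94B–$40.94B damage trajectory is orders of magnitude above
deaths × any stated VSL and its basis (discounting, cumulative deaths,
climate damages) is unstated, so it is not a reproduction target.

## Synthetic generator

`generate_panel` emulates a national deposition panel: expected national
waste in year y is `population0·(1+g)^y · waste_per_capita · 365 / 1e6` Gg,
split across sites by fixed shares and perturbed by mean-preserving
multiplicative lognormal noise (σ² = ln(1+CV²)). Defaults — 10.5M people,
3%/yr growth, 0.835 kg/person/day, three sites (0.5/0.3/0.2), CV 5% —
give ~3,200 Gg/yr around 2020, matching the national scale of the
published waste table. Per-site DOC is drawn uniformly from (0.12, 0.20)
and MCF from its physical range [0.4, 1.0]; DOCf and F stay at the
conventional 0.5, with no recovery or oxidation (the pre-intervention
situation). The generator does **not** emulate policy shocks, composition
shifts, reporting discontinuities, or the year-to-year volatility visible
in the real national series — passing tests demonstrate internal
consistency of the pipeline, not fidelity to any particular year's
statistics.

`recovery_harness` checks identifiability: per-year emissions are
simulated from the mass-balance model with lognormal noise and DOC (the
only unknown) is re-estimated as the least-squares slope of observations
on unit-DOC predictions. Because the noise is mean-1 and independent of
the design, the estimator is unbiased; tests verify exact recovery at
zero noise, |relative bias| < 1% at CV 5% with 200 replicates, and RMSE
decreasing across panel lengths of 4, 16 and 64 years. Monte-Carlo sizes
(200–300 replicates, ≤64-year panels) keep the whole suite to a few
seconds while leaving wide margins on these assertions.

## Numerical conventions and degenerate inputs

- Internal canonical mass unit is Gg (= 1000 t = 1 kt); strategy series in
  tons/yr are stored as published and converted on demand.
- Series values must be finite and ≥ 0; years strictly increasing; unit
  mixing in arithmetic raises rather than coerces.
- CSV series IO uses round-trip float parsing, so write→read is exact.
- Percentages display to the nearest integer and emissions to two
  decimals, matching the source's reporting style; full-precision values
  are always available programmatically.
- Degenerate inputs (empty series, empty CSV, zero baseline, all-zero
  panels, out-of-range parameters) raise typed errors
  (`ValidationError`, `ConfigurationError`, `YearRangeError`,
  `UnitMismatchError`, `FixtureIntegrityError`).

## Known data quirks (preserved, not repaired)

- The 2020–2023 national waste totals exceed the sum of the two reporting
  authorities' rows (2020: 3170.2 vs printed 3251.4); the bundle stores
  all three rows as published and performs no reconciliation.
- Combined-scenario reduction claims of 34% by 2040 and 55% by 2050
  cannot be composed from the published phase series and are not modelled.

## Limitations

Single-gas (CH4 only); no atmospheric chemistry or transport; no
age-stratified mortality; no morbidity costs, productivity losses or
property-value effects in the valuation; instant-release emission timing;
strategy trajectories are inputs, not model outputs.
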