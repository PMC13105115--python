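# landfillch4

Landfill methane accounting, mitigation-scenario wedge analysis and
ozone-mediated health damages for a national municipal-solid-waste (MSW)
system, built around the Jordan case: roughly 3 million tonnes of MSW per
year, ~90% landfilled, with the stream growing about 3%/yr with population
and income. It is aimed at waste-sector and environmental-health analysts
who need a transparent, testable version of the accounting that planning
platforms (LEAP, WasteMAP) perform internally.

## What it computes

**Emissions.** Two printed-form estimators of annual landfill methane:

- the site-summed Total Annual Methane Emissions equation
  `TAME = Σ_i [MSW_i · FDOC_i · FD_i · MEF_i · CR_i − MR_i]`, and
- the IPCC-style mass-balance form
  `CH4 = Σ_x [MSW_x · MCF · DOC · DOCf · F · 16/12 · (1−R) · (1−OX)]`,

with MSW in Gg/yr, DOC the degradable organic carbon fraction, MCF the
methane correction factor (0.4 unmanaged shallow … 1.0 managed anaerobic),
F the methane fraction of landfill gas (0.5), and R/OX the recovered and
cover-oxidized fractions. CH4 mass converts to CO2-equivalent via a GWP
factor (default 25, the waste-sector convention; 28 selectable).

**Scenarios.** Mitigation interventions are wedges against a baseline
CO2e trajectory anchored at 2022/2030/2040/2050 and interpolated
geometrically. Wedges are absolute (kt CO2e/yr at milestone years) or
fractions of the baseline; the package reproduces the published short-term
(−12% by 2030), mid-term (−8.5% of baseline by 2040) and long-term phases,
the activity-reduction ledger sums, and the comparison of five
waste-diversion strategies (incineration with energy recovery, composting,
anaerobic digestion, recycling) against a no-action baseline.

**Health and valuation.** Emitted methane drives ground-level ozone, and
the burden model is linear: deaths/yr and asthma hospital visits/yr per Gg
CH4/yr, either the UNEP Global Methane Assessment benchmark (1,400 deaths
per Mt) or factors calibrated on the published 2022 anchor row. Mortality
is monetized with a value of statistical life (VSL): WTP divided by risk
reduction, transferred across income levels as
`VSL_target = VSL_ref · (income_target/income_ref)^elasticity`
(default elasticity 0.85; Jordan default VSL $1.3M).

**Synthetic data.** A seeded generator produces multi-site annual waste
panels (population-driven ~3%/yr growth, fixed site shares, multiplicative
lognormal noise) plus per-site emission parameters, and a recovery harness
verifies the DOC fraction is identifiable from noisy panel emissions.

## Worked example

```python
>>> import landfillch4 as lc
>>> bundle = lc.load_fixtures()
>>> lc.mass_from_co2e(bundle.table4_baseline[2022], lc.GWPConvention(25))
172.7032
```

4,317.58 kt CO2e in 2022 is 172.70 Gg of physical methane — the published
"173 thousand metric tons". Applying the short-term wedge portfolio at
2030:

```python
>>> ledger = lc.default_intervention_ledger()
>>> net, _ = lc.apply_interventions(bundle.table4_baseline,
...                                 ledger[lc.Phase.SHORT_TERM], 2030)
>>> round(net, 2), round(lc.percent_reduction(bundle.table4_baseline[2030], net))
(4424.65, 12)
```

i.e. the 5,028.02 kt CO2e baseline falls to 4,424.65, a 12% reduction.
The calibrated health response applied to the 2050 methane mass:

```python
>>> resp = lc.calibrate_response(bundle.table7_mass[2022],
...                              bundle.table7_deaths[2022],
...                              bundle.table7_asthma[2022])
>>> mass50 = lc.AnnualSeries("Gg_CH4", {2050: lc.mass_from_co2e(7769.88)})
>>> lc.compute_burden(mass50, resp)[0].deaths_display
440
```

440 premature deaths/yr attributable to ozone from this source by 2050,
up from 245 in 2022 — about $572M/yr of mortality damages at the $1.3M VSL.

The same stages are exposed as a CLI:

```sh
landfillch4 report --out out/         # all CSV tables + summary.json
landfillch4 emissions --gwp 28        # baseline table to stdout
landfillch4 simulate --seed 1 --out out/   # synthetic waste panel
```

## Layout

- `src/landfillch4/core.py` — units, `AnnualSeries`, records, CSV IO
- `src/landfillch4/fixtures.py` — the bundled published tables
- `src/landfillch4/emissions.py` — TAME, mass-balance, GWP, interpolation
- `src/landfillch4/scenarios.py` — wedges, ledger sums, strategy comparison
- `src/landfillch4/health.py` — linear exposure-response burden
- `src/landfillch4/valuation.py` — VSL construction and monetization
- `src/landfillch4/synthetic.py` — panel generator and recovery harness
- `src/landfillch4/report.py`, `cli.py` — run configs, report, CLI

See `docs/methods.md` for modelling assumptions and known limitations.
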