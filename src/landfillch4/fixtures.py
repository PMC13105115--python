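"""Bundled Jordan waste, socioeconomic, emission and health tables.

The study dataset is small enough to carry in source: national waste
landfilled 2019-2023, socioeconomic projections to 2050, the LEAP baseline
CO2e anchors, the mitigation-activity reduction ledger, five WasteMAP-style
strategy emission series (2025-2050), and the health-impact table. Values
are stored exactly as published; :func:`load_fixtures` verifies them against
embedded checks and raises :class:`FixtureIntegrityError` naming the table
if the bundle has been corrupted.

Known quirks of the source, preserved rather than reconciled:

* the 2020-2023 national totals exceed the sum of the two reporting
  authorities' rows (e.g. 2020: 1795.4 + 1374.8 = 3170.2 vs printed 3251.4);
* the mid-term ledger subtotal is printed as 1489.94 though its components
  sum to 1489.95; the grand total 4335.39 is the sum of the printed
  subtotals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple, Union

import pandas as pd

from .core import (
    AnnualSeries,
    FixtureIntegrityError,
    SocioeconProjection,
    Unit,
    WasteRecord,
)
from .scenarios import Intervention, Phase, WedgeMode

__all__ = [
    "FixtureBundle",
    "load_fixtures",
    "default_intervention_ledger",
    "export_fixture_csvs",
    "SHORT_TERM_COMPONENTS_2030",
    "SHORT_TERM_TOTAL_2030",
    "MID_TERM_FRACTIONS",
]

# -- Table 1: municipal solid waste landfilled (thousand tonnes/yr = Gg/yr) --

_TABLE1 = {
    # site_id -> {year: Gg}
    "MoLA": {2019: 1663.0, 2020: 1795.4, 2021: 2649.5, 2022: 2914.4, 2023: 1732.4},
    "GAM": {2019: 1456.0, 2020: 1374.8, 2021: 1350.5, 2022: 1368.9, 2023: 1406.0},
    "Total": {2019: 3119.0, 2020: 3251.4, 2021: 4105.5, 2022: 4370.5, 2023: 3188.5},
}

# -- Table 2: socioeconomic and health context ------------------------------

_TABLE2 = [
    # year, population (m), pop growth %/yr, gdp (bn USD), gdp growth %/yr,
    # average income (USD/person), ozone relative risk
    (2022, 11.345, 2.0, 49.375, 2.4, 4352.1375, 1.04),
    (2030, 13.45124, 2.32909, 60.210, 2.83342, 4476.179, 1.04),
    (2040, 16.72135, 2.895311, 76.325, 3.591786, 4564.55, 1.04),
    (2050, 20.78645, 3.599185, 96.754, 4.55313, 4654.667, 1.04),
]

# -- Table 4: baseline methane inventory anchors (kt CO2e) ------------------

_TABLE4 = {2022: 4317.58, 2030: 5028.02, 2040: 6250.37, 2050: 7769.88}

# -- Table 5: activity reduction ledger (kt CO2e in 2050) -------------------

_TABLE5 = [
    # (id, title, phase, 2050 reduction, counted_in_subtotal)
    ("st1_salt_biogas", "Biogas from Salt Treatment Plant", Phase.SHORT_TERM, 19.87, False),
    ("st2_recycling_banks", "Recycling Bank Project in Amman", Phase.SHORT_TERM, 301.68, True),
    ("st3_mbt_plant", "Organic Waste Processing Plant (MBT) in Amman", Phase.SHORT_TERM, 301.68, True),
    ("st4_informal_collectors", "Regulation of Informal Waste Collectors", Phase.SHORT_TERM, 150.84, True),
    ("st5_rua_operations", "Enhancing Operations of RUA Waste Management Company", Phase.SHORT_TERM, 150.84, True),
    ("st6_akeider_gas", "Methane Gas Collection at Al-Ekeider Landfill", Phase.SHORT_TERM, 754.2, True),
    ("st7_awareness", "Management of Studies and Awareness on Solid Waste", Phase.SHORT_TERM, 150.84, True),
    ("mt1_sanitary_landfills", "Transforming Landfills into Engineered Sanitary Landfills", Phase.MID_TERM, 876.44, True),
    ("mt2_transfer_stations", "Development of Waste Transfer Stations", Phase.MID_TERM, 175.29, True),
    ("mt3_gps_guidance", "GPS-Based Guidance System", Phase.MID_TERM, 87.64, True),
    ("mt4_national_center", "National Waste Management Center", Phase.MID_TERM, 175.29, True),
    ("mt5_husainiyat_biogas", "Biogas Collection from Al-Husainiyat Landfill", Phase.MID_TERM, 175.29, True),
    ("lt1_circular_economy", "Promoting Circular Economy for Waste", Phase.LONG_TERM, 172.56, True),
    ("lt2_cement_biomass", "Utilizing Biomass in Cement Factories", Phase.LONG_TERM, 862.81, True),
]

#: Phase subtotals and grand total as printed in the source ledger. The
#: grand total equals the sum of the three printed subtotals.
_TABLE5_PRINTED_SUBTOTALS = {
    Phase.SHORT_TERM: 1810.08,
    Phase.MID_TERM: 1489.94,
    Phase.LONG_TERM: 1035.37,
}
_TABLE5_PRINTED_GRAND_TOTAL = 4335.39

# -- Table 6: strategy emission series (tons CH4/yr, 2025-2050) -------------

_TABLE6_YEARS = (2025, 2030, 2035, 2040, 2045, 2050)
_TABLE6 = {
    "baseline": (59500, 66300, 73000, 79700, 86500, 93500),
    "composting_focus": (59500, 54500, 51200, 49500, 49000, 49500),
    "recycling_focus": (59500, 57400, 56600, 56900, 58300, 60400),
    "anaerobic_digestion": (59500, 55400, 53000, 52000, 52200, 53300),
    "incineration_energy_recovery": (59500, 53400, 49000, 46400, 45100, 44900),
}

# -- Table 7: estimated health impacts of landfill methane ------------------

_TABLE7_YEARS = (2022, 2030, 2040, 2050)
_TABLE7_MASS = (173.0, 201.0, 250.0, 311.0)  # thousand tonnes CH4 (Gg)
_TABLE7_DEATHS = (245.0, 285.0, 354.0, 440.0)
_TABLE7_ASTHMA = (744.0, 866.0, 1076.0, 1338.0)

# -- Scenario-narrative milestone values ------------------------------------

#: Individual short-term project reductions at 2030 (kt CO2e/yr) from the
#: scenario narrative. Informational: they sum to 607.4, not the printed
#: total reduction 603.37 (= baseline 5028.02 minus net 4424.65), which is
#: authoritative for scenario arithmetic.
SHORT_TERM_COMPONENTS_2030: Dict[str, float] = {
    "st2_recycling_banks": 100.0,
    "st3_mbt_plant": 100.0,
    "st4_informal_collectors": 52.0,
    "st5_rua_operations": 52.0,
    "st6_akeider_gas": 251.40,
    "st7_awareness": 52.0,
}

#: Total short-term reduction at 2030 implied by the printed net (authoritative).
SHORT_TERM_TOTAL_2030 = 603.37

#: Mid-term wedges as fractions of baseline. The narrative's 2030 and 2040
#: milestone reductions (251.4 -> 312.52, 50.28 -> 62.50, 25.14 -> 31.25, ...)
#: are exactly these fractions of the respective baseline anchors, so the
#: wedges are encoded fractionally and scale with the baseline.
MID_TERM_FRACTIONS: Dict[str, Tuple[str, float]] = {
    "mt1_sanitary_landfills": ("Transforming Landfills into Engineered Sanitary Landfills", 0.05),
    "mt2_transfer_stations": ("Development of Waste Transfer Stations", 0.01),
    "mt3_gps_guidance": ("GPS-Based Guidance System", 0.005),
    "mt4_national_center": ("National Waste Management Center", 0.01),
    "mt5_husainiyat_biogas": ("Biogas Collection from Al-Husainiyat Landfill", 0.01),
}

#: Long-term wedges, absolute kt CO2e at 2050, following the activity ledger.
_LONG_TERM_ABSOLUTE_2050: Dict[str, Tuple[str, float]] = {
    "lt1_circular_economy": ("Promoting Circular Economy for Waste", 172.56),
    "lt2_cement_biomass": ("Utilizing Biomass in Cement Factories", 862.81),
}


@dataclass(frozen=True)
class FixtureBundle:
    """The complete in-source dataset, one attribute per published table."""

    table1: List[WasteRecord]
    table2: List[SocioeconProjection]
    table4_baseline: AnnualSeries  # kt CO2e anchors
    table5_ledger: List[Intervention]  # 2050 reductions, kt CO2e
    table5_printed_subtotals: Dict[Phase, float]
    table5_printed_grand_total: float
    table6: Dict[str, AnnualSeries]  # tons CH4/yr strategy series
    table7_mass: AnnualSeries  # Gg CH4
    table7_deaths: AnnualSeries
    table7_asthma: AnnualSeries

    def table1_total(self, year: int) -> float:
        """National total waste landfilled (Gg) for a year, as printed."""
        for rec in self.table1:
            if rec.site_id == "Total" and rec.year == year:
                return rec.msw_mass
        raise KeyError(f"no national total for year {year}")


def _build_bundle() -> FixtureBundle:
    table1 = [
        WasteRecord(site_id=site, year=year, msw_mass=mass)
        for site, series in _TABLE1.items()
        for year, mass in series.items()
    ]
    table2 = [SocioeconProjection(*row) for row in _TABLE2]
    table4 = AnnualSeries(Unit.KT_CO2E, _TABLE4)
    ledger = [
        Intervention(
            id=iid, title=title, phase=phase, mode=WedgeMode.ABSOLUTE,
            schedule={2050: reduction}, counted_in_subtotal=counted,
        )
        for iid, title, phase, reduction, counted in _TABLE5
    ]
    table6 = {
        name: AnnualSeries(Unit.TONS_PER_YEAR, zip(_TABLE6_YEARS, vals))
        for name, vals in _TABLE6.items()
    }
    return FixtureBundle(
        table1=table1,
        table2=table2,
        table4_baseline=table4,
        table5_ledger=ledger,
        table5_printed_subtotals=dict(_TABLE5_PRINTED_SUBTOTALS),
        table5_printed_grand_total=_TABLE5_PRINTED_GRAND_TOTAL,
        table6=table6,
        table7_mass=AnnualSeries(Unit.GG_CH4, zip(_TABLE7_YEARS, _TABLE7_MASS)),
        table7_deaths=AnnualSeries(Unit.PERSONS, zip(_TABLE7_YEARS, _TABLE7_DEATHS)),
        table7_asthma=AnnualSeries(Unit.PERSONS, zip(_TABLE7_YEARS, _TABLE7_ASTHMA)),
    )


def _verify(bundle: FixtureBundle) -> None:
    """Cross-check the bundle against published spot values."""
    checks = [
        ("table1", abs(bundle.table1_total(2019) - 3119.0) < 1e-12),
        ("table1", abs(bundle.table1_total(2022) - 4370.5) < 1e-12),
        ("table4", bundle.table4_baseline.as_dict()
         == {2022: 4317.58, 2030: 5028.02, 2040: 6250.37, 2050: 7769.88}),
        ("table5", abs(sum(
            iv.schedule[2050] for iv in bundle.table5_ledger
            if iv.phase is Phase.LONG_TERM) - 1035.37) < 1e-9),
        ("table5", abs(sum(bundle.table5_printed_subtotals.values())
                       - bundle.table5_printed_grand_total) < 1e-9),
        ("table6", bundle.table6["baseline"][2025] == 59500.0),
        ("table6", bundle.table6["incineration_energy_recovery"][2050] == 44900.0),
        ("table7", bundle.table7_deaths[2022] == 245.0),
    ]
    for table, ok in checks:
        if not ok:
            raise FixtureIntegrityError(f"bundled data for {table} is corrupted")


def load_fixtures() -> FixtureBundle:
    """Build and integrity-check the complete published dataset."""
    bundle = _build_bundle()
    _verify(bundle)
    return bundle


def default_intervention_ledger() -> Dict[Phase, List[Intervention]]:
    """The study's default scenario wedges, keyed by phase.

    Short-term: one combined absolute wedge carrying the authoritative total
    2030 reduction. Mid-term: five fraction-of-baseline wedges. Long-term:
    two absolute wedges at their 2050 ledger values.
    """
    short = [
        Intervention(
            id="short_term_portfolio",
            title="Combined short-term projects (recycling, MBT, gas collection, regulation, awareness)",
            phase=Phase.SHORT_TERM,
            mode=WedgeMode.ABSOLUTE,
            schedule={2030: SHORT_TERM_TOTAL_2030},
        )
    ]
    mid = [
        Intervention(
            id=iid, title=title, phase=Phase.MID_TERM,
            mode=WedgeMode.FRACTION_OF_BASELINE, schedule={2030: frac},
        )
        for iid, (title, frac) in MID_TERM_FRACTIONS.items()
    ]
    long = [
        Intervention(
            id=iid, title=title, phase=Phase.LONG_TERM,
            mode=WedgeMode.ABSOLUTE, schedule={2050: value},
        )
        for iid, (title, value) in _LONG_TERM_ABSOLUTE_2050.items()
    ]
    return {Phase.SHORT_TERM: short, Phase.MID_TERM: mid, Phase.LONG_TERM: long}


def export_fixture_csvs(outdir: Union[str, Path]) -> List[Path]:
    """Write every bundled table as a plain CSV for inspection."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = load_fixtures()
    written: List[Path] = []

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        written.append(path)

    _write("table1_waste", pd.DataFrame(
        [(r.site_id, r.year, r.msw_mass) for r in bundle.table1],
        columns=["site_id", "year", "msw_mass_Gg"]))
    _write("table2_socioeconomic", pd.DataFrame(
        [vars(p) for p in bundle.table2]))
    _write("table4_baseline_anchors", bundle.table4_baseline.to_frame()
           .rename(columns={"value": "kt_CO2e"}))
    _write("table5_ledger", pd.DataFrame(
        [(iv.id, iv.title, iv.phase.value, iv.schedule[2050], iv.counted_in_subtotal)
         for iv in bundle.table5_ledger],
        columns=["id", "title", "phase", "reduction_2050_kt_CO2e", "counted_in_subtotal"]))
    _write("table6_strategies", pd.DataFrame(
        {"year": bundle.table6["baseline"].years,
         **{name: series.values for name, series in bundle.table6.items()}}))
    _write("table7_health", pd.DataFrame(
        {"year": bundle.table7_mass.years,
         "methane_mass_Gg": bundle.table7_mass.values,
         "premature_deaths": bundle.table7_deaths.values,
         "asthma_visits": bundle.table7_asthma.values}))
    return written
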