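"""Run configuration and end-to-end report assembly.

Ties the stages together: waste input (bundled tables, a user CSV, or the
synthetic generator) -> annual methane mass -> CO2e baseline -> scenario
wedges -> health burden -> monetized mortality. Every number in the JSON
summary is produced by a module operation; this layer only formats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import pandas as pd
import yaml

from .core import (
    AnnualSeries,
    ConfigurationError,
    Unit,
    read_series_csv,
)
from .emissions import (
    FODParameters,
    GWPConvention,
    baseline_series,
    co2e_from_mass,
    compute_fod,
    mass_from_co2e,
)
from .fixtures import default_intervention_ledger, load_fixtures
from .health import calibrate_response, compute_burden, burden_frame, unep_response
from .scenarios import (
    Phase,
    apply_interventions,
    build_scenario,
    compare_strategies,
    ledger_subtotal,
    percent_reduction,
)
from .synthetic import GeneratorConfig, generate_panel
from .valuation import (
    DEFAULT_JORDAN_VSL,
    damage_frame,
    mortality_cost,
    vsl_from_wtp,
)

__all__ = ["RunConfig", "emissions_table", "scenario_tables", "health_table",
           "damage_table", "report_summary", "run_report"]


@dataclass
class RunConfig:
    """Run settings. Exactly one waste source must be active.

    ``source`` is ``fixtures`` (bundled published tables), ``csv`` (a
    year,value deposition series in Gg plus mass-balance parameters), or
    ``generator`` (the synthetic panel generator).
    """

    source: str = "fixtures"
    waste_csv: Optional[Path] = None
    fod_params: FODParameters = field(
        default_factory=lambda: FODParameters(mcf=1.0, doc=0.15, docf=0.5)
    )
    generator: Optional[GeneratorConfig] = None
    gwp: GWPConvention = field(default_factory=GWPConvention)
    response: str = "calibrated_table7"  # or "unep"
    vsl: float = DEFAULT_JORDAN_VSL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.source not in ("fixtures", "csv", "generator"):
            raise ConfigurationError(
                f"source must be fixtures, csv or generator, got {self.source!r}"
            )
        if self.source == "csv" and self.waste_csv is None:
            raise ConfigurationError("source=csv requires waste_csv")
        if self.source != "csv" and self.waste_csv is not None:
            raise ConfigurationError("waste_csv given but source is not csv")
        if self.source == "generator" and self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)
        if self.source != "generator" and self.generator is not None:
            raise ConfigurationError("generator config given but source is not generator")
        if self.response not in ("calibrated_table7", "unep"):
            raise ConfigurationError(
                f"response must be calibrated_table7 or unep, got {self.response!r}"
            )

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "gwp" in data and not isinstance(data["gwp"], GWPConvention):
            data["gwp"] = GWPConvention(factor=float(data["gwp"]))
        if "fod_params" in data and isinstance(data["fod_params"], dict):
            data["fod_params"] = FODParameters(**data["fod_params"])
        if "generator" in data and isinstance(data["generator"], dict):
            data["generator"] = GeneratorConfig(**data["generator"])
        if "waste_csv" in data and data["waste_csv"] is not None:
            data["waste_csv"] = Path(data["waste_csv"])
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)


def _mass_series(config: RunConfig) -> AnnualSeries:
    """Annual emitted methane mass (Gg CH4) under the configured source."""
    if config.source == "fixtures":
        bundle = load_fixtures()
        co2e = baseline_series(bundle.table4_baseline)
        return AnnualSeries(
            Unit.GG_CH4,
            ((y, mass_from_co2e(v, config.gwp)) for y, v in co2e),
        )
    if config.source == "csv":
        deposits = read_series_csv(config.waste_csv, Unit.GG_CH4)
        return AnnualSeries(
            Unit.GG_CH4,
            (
                (y, compute_fod({y: m}, config.fod_params))
                for y, m in deposits
            ),
        )
    # generator
    records, params = generate_panel(config.generator)
    per_year: Dict[int, float] = {}
    for rec in records:
        per_year[rec.year] = per_year.get(rec.year, 0.0) + compute_fod(
            {rec.year: rec.msw_mass}, params[rec.site_id]
        )
    return AnnualSeries(Unit.GG_CH4, per_year)


def emissions_table(config: RunConfig) -> pd.DataFrame:
    """Baseline emission table: year, CH4 mass (Gg), CO2e (kt)."""
    mass = _mass_series(config)
    return pd.DataFrame(
        {
            "year": mass.years,
            "ch4_Gg": mass.values,
            "co2e_kt": [co2e_from_mass(v, config.gwp) for v in mass.values],
        }
    )


def _response(config: RunConfig):
    if config.response == "unep":
        return unep_response()
    bundle = load_fixtures()
    return calibrate_response(
        bundle.table7_mass[2022],
        bundle.table7_deaths[2022],
        bundle.table7_asthma[2022],
        ozone_rr=bundle.table2[0].ozone_rr,
    )


def scenario_tables(config: RunConfig) -> Dict[str, pd.DataFrame]:
    """Scenario outputs: phased wedge trajectory and strategy comparison."""
    bundle = load_fixtures()
    ledger = default_intervention_ledger()
    interventions = [iv for phase in ledger.values() for iv in phase]
    result = build_scenario(bundle.table4_baseline, interventions)
    trajectory = pd.DataFrame(
        {
            "year": result.baseline.years,
            "baseline_kt_co2e": result.baseline.values,
            "net_kt_co2e": result.net.values,
            **{
                f"reduction_{k}": s.values
                for k, s in result.per_intervention_reduction.items()
            },
        }
    )
    strategies = compare_strategies(bundle.table6, "baseline", year=2050)
    return {"trajectory": trajectory, "strategies_2050": strategies}


def health_table(config: RunConfig) -> pd.DataFrame:
    burdens = compute_burden(_mass_series(config), _response(config))
    frame = burden_frame(burdens)
    frame.insert(1, "ch4_Gg", list(_mass_series(config).values))
    return frame


def damage_table(config: RunConfig) -> pd.DataFrame:
    burdens = compute_burden(_mass_series(config), _response(config))
    return damage_frame(mortality_cost(burdens, config.vsl))


def report_summary(config: RunConfig) -> dict:
    """Headline quantities of the full analysis, all module-computed."""
    bundle = load_fixtures()
    gwp = config.gwp
    anchors = bundle.table4_baseline
    ledger = default_intervention_ledger()

    mass_2022 = mass_from_co2e(anchors[2022], gwp)
    mass_2050 = mass_from_co2e(anchors[2050], gwp)

    st_net, _ = apply_interventions(anchors, ledger[Phase.SHORT_TERM], 2030)
    mt_net, _ = apply_interventions(anchors, ledger[Phase.MID_TERM], 2040)

    response = _response(config)
    mass = _mass_series(
        RunConfig(source="fixtures", gwp=gwp, response=config.response, vsl=config.vsl)
    )
    burdens = compute_burden(mass, response)
    by_year = {b.year: b for b in burdens}
    damages = mortality_cost(burdens, config.vsl)
    dmg_2050 = next(d for d in damages if d.year == 2050)

    strategies = compare_strategies(bundle.table6, "baseline", 2050)
    strat = {
        row.strategy: row.percent_display for row in strategies.itertuples()
    }

    return {
        "baseline_2022_kt_co2e": anchors[2022],
        "baseline_2050_kt_co2e": anchors[2050],
        "ch4_mass_2022_Gg": round(mass_2022, 2),
        "ch4_mass_2050_Gg": round(mass_2050, 2),
        "mass_increase_2022_2050_percent": round(
            100.0 * (mass_2050 / mass_2022 - 1.0), 2
        ),
        "short_term_2030_net_kt_co2e": round(st_net, 2),
        "short_term_2030_percent_reduction": round(
            percent_reduction(anchors[2030], st_net), 1
        ),
        "mid_term_2040_net_kt_co2e": round(mt_net, 2),
        "ledger_long_term_subtotal_kt_co2e": round(
            ledger_subtotal(bundle.table5_ledger, Phase.LONG_TERM), 2
        ),
        "ledger_grand_total_kt_co2e": round(
            sum(bundle.table5_printed_subtotals.values()), 2
        ),
        "strategy_percent_reduction_2050": strat,
        "premature_deaths_2050": by_year[2050].deaths_display,
        "asthma_visits_2050": by_year[2050].asthma_display,
        "mortality_cost_2050_usd": dmg_2050.mortality_cost,
        "vsl_worked_example_usd": vsl_from_wtp(300.0, 1e-4),
        "vsl_used_usd": config.vsl,
        "gwp_factor": gwp.factor,
        "seed": config.seed,
    }


def run_report(config: RunConfig, outdir: Union[str, Path]) -> Path:
    """Write the full CSV set and JSON summary; returns the summary path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    emissions_table(config).to_csv(outdir / "emissions_baseline.csv", index=False)
    for name, frame in scenario_tables(config).items():
        frame.to_csv(outdir / f"scenario_{name}.csv", index=False)
    health_table(config).to_csv(outdir / "health_burden.csv", index=False)
    damage_table(config).to_csv(outdir / "mortality_damages.csv", index=False)
    summary = report_summary(config)
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary_path
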