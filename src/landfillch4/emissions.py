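"""Landfill methane emission equations and CO2-equivalent conversion.

Two printed-form estimators are implemented:

* the site-summed Total Annual Methane Emissions (TAME) equation,
  ``TAME = sum_i [MSW_i * FDOC_i * FD_i * MEF_i * CR_i - MR_i]``; and
* the IPCC-style mass-balance form used for strategy projections,
  ``CH4 = sum_x [MSW_x * MCF * DOC * DOCf * F * 16/12 * (1-R) * (1-OX)]``.

The mass-balance form carries the IPCC first-order-decay parameter names but,
as used here, has no decay constant: every tonne deposited in year x emits in
year x (an instant-release approximation). Time-lagged decay kinetics are a
non-goal.

Also provided: GWP-based conversion between Gg CH4 and kt CO2e, and
interpolation of a baseline trajectory between sparse anchor years.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .core import (
    AnnualSeries,
    ConfigurationError,
    Unit,
    ValidationError,
    WasteRecord,
    YearRangeError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TAMEParameters",
    "FODParameters",
    "GWPConvention",
    "CH4_PER_C",
    "compute_tame",
    "compute_fod",
    "co2e_from_mass",
    "mass_from_co2e",
    "interpolate_baseline",
    "baseline_series",
]

#: Stoichiometric CH4/C mass ratio (16 g/mol CH4 per 12 g/mol C).
CH4_PER_C = 16.0 / 12.0


def _check_fraction(name: str, value: float, low: float = 0.0, high: float = 1.0) -> None:
    if not (low <= value <= high):
        raise ValidationError(f"{name} must be in [{low}, {high}], got {value}")


@dataclass(frozen=True)
class TAMEParameters:
    """Per-site coefficients of the TAME equation.

    ``mef`` (methane emission factor) defaults to 1.0: it is a dimensionless
    site multiplier with no tabulated national value, so the neutral default
    leaves the degradable-carbon terms in charge. ``cr`` defaults to the
    stoichiometric 16/12 carbon-to-methane conversion. ``mr`` is annual
    methane recovered at the site, in Gg CH4/yr.
    """

    fdoc: float
    fd: float
    mef: float = 1.0
    cr: float = CH4_PER_C
    mr: float = 0.0

    def __post_init__(self) -> None:
        _check_fraction("fdoc", self.fdoc)
        _check_fraction("fd", self.fd)
        if self.mef < 0:
            raise ValidationError(f"mef must be >= 0, got {self.mef}")
        if self.cr <= 0:
            raise ValidationError(f"cr must be > 0, got {self.cr}")
        if self.mr < 0:
            raise ValidationError(f"mr must be >= 0, got {self.mr}")


@dataclass(frozen=True)
class FODParameters:
    """Coefficients of the mass-balance (IPCC) methane equation.

    ``mcf`` reflects site management quality and ranges from 0.4 (unmanaged
    shallow) to 1.0 (managed anaerobic). ``f`` is the methane volume fraction
    of landfill gas, typically 0.5. ``r`` and ``ox`` are the recovered and
    cover-oxidized fractions of generated methane.
    """

    mcf: float
    doc: float
    docf: float
    f: float = 0.5
    r: float = 0.0
    ox: float = 0.0

    def __post_init__(self) -> None:
        _check_fraction("mcf", self.mcf, 0.4, 1.0)
        _check_fraction("doc", self.doc)
        _check_fraction("docf", self.docf)
        _check_fraction("f", self.f)
        _check_fraction("r", self.r)
        _check_fraction("ox", self.ox)

    @property
    def yield_per_gg(self) -> float:
        """Gg CH4 emitted per Gg waste deposited."""
        return (
            self.mcf * self.doc * self.docf * self.f * CH4_PER_C
            * (1.0 - self.r) * (1.0 - self.ox)
        )


@dataclass(frozen=True)
class GWPConvention:
    """Global warming potential used to express CH4 mass as CO2e.

    The default factor 25 is the value common in waste-sector reporting;
    28 (a more recent 100-year value) is selectable.
    """

    factor: float = 25.0
    horizon_years: int = 100

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValidationError(f"GWP factor must be > 0, got {self.factor}")


def compute_tame(
    records: Iterable[WasteRecord],
    params: Mapping[str, TAMEParameters],
) -> float:
    """Total annual methane emissions (Gg CH4/yr) across sites for one year.

    Each site contributes ``MSW*FDOC*FD*MEF*CR - MR``; a site whose recovery
    exceeds its gross generation is floored at zero (with a warning) before
    summation, since a landfill cannot emit negative mass.
    """
    records = list(records)
    years = {r.year for r in records}
    if len(years) > 1:
        raise ValidationError(f"records span multiple years: {sorted(years)}")
    total = 0.0
    for rec in records:
        p = params.get(rec.site_id)
        if p is None:
            raise ConfigurationError(f"no TAME parameters for site {rec.site_id!r}")
        gross = rec.msw_mass * p.fdoc * p.fd * p.mef * p.cr
        net = gross - p.mr
        if net < 0:
            logger.warning(
                "site %s: recovery %.4g Gg exceeds gross generation %.4g Gg; "
                "flooring at 0", rec.site_id, p.mr, gross,
            )
            net = 0.0
        total += net
    return total


def compute_fod(
    deposits: Mapping[int, float],
    params: FODParameters,
) -> float:
    """Methane emitted (Gg CH4) from a deposition history, mass-balance form.

    ``deposits`` maps deposition year -> Gg waste landfilled that year. Under
    the printed instant-release form the result is simply the parameter yield
    applied to the summed deposits.
    """
    total_waste = 0.0
    for year, mass in deposits.items():
        if not math.isfinite(mass) or mass < 0:
            raise ValidationError(f"deposit for year {year} must be >= 0, got {mass}")
        total_waste += mass
    return total_waste * params.yield_per_gg


def co2e_from_mass(mass: float, gwp: GWPConvention = GWPConvention()) -> float:
    """Convert Gg CH4 to kt CO2e (multiply by the GWP factor)."""
    if mass < 0:
        raise ValidationError(f"mass must be >= 0, got {mass}")
    return mass * gwp.factor


def mass_from_co2e(co2e: float, gwp: GWPConvention = GWPConvention()) -> float:
    """Convert kt CO2e back to Gg CH4 (divide by the GWP factor)."""
    if co2e < 0:
        raise ValidationError(f"co2e must be >= 0, got {co2e}")
    return co2e / gwp.factor


def interpolate_baseline(
    anchors: AnnualSeries,
    year: int,
    mode: str = "geometric",
) -> float:
    """Value of a baseline trajectory at ``year``, between printed anchors.

    Anchor years return the anchor exactly. Interior years are filled between
    the bracketing anchors either geometrically (constant annual growth rate,
    the default, matching compound population/GDP growth) or linearly. No
    extrapolation: a year outside the anchor span raises
    :class:`YearRangeError`. Geometric interpolation falls back to linear on
    a zero-valued bracket, where a growth rate is undefined.
    """
    if mode not in ("geometric", "linear"):
        raise ConfigurationError(f"interpolation mode must be geometric or linear, got {mode!r}")
    year = int(year)
    if year < anchors.first_year or year > anchors.last_year:
        raise YearRangeError(
            f"year {year} outside anchor range "
            f"[{anchors.first_year}, {anchors.last_year}]"
        )
    if year in anchors:
        return anchors[year]
    years = anchors.years
    i = bisect_right(years, year)
    y0, y1 = years[i - 1], years[i]
    v0, v1 = anchors[y0], anchors[y1]
    t = (year - y0) / (y1 - y0)
    if mode == "geometric" and v0 > 0 and v1 > 0:
        return v0 * (v1 / v0) ** t
    return v0 + t * (v1 - v0)


def baseline_series(
    anchors: AnnualSeries,
    years: Optional[Iterable[int]] = None,
    mode: str = "geometric",
) -> AnnualSeries:
    """Densify an anchored baseline to an annual series over ``years``.

    Defaults to every year from the first to the last anchor.
    """
    if years is None:
        years = range(anchors.first_year, anchors.last_year + 1)
    return AnnualSeries(
        anchors.unit,
        ((y, interpolate_baseline(anchors, y, mode)) for y in years),
    )
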