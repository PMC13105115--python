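"""Core domain types for landfill-methane accounting.

Defines the year-indexed :class:`AnnualSeries` container with strict unit
discipline, the raw waste and socioeconomic records, and CSV readers/writers
for series data. All downstream stages (emission equations, scenario wedges,
health burden, valuation) exchange data through these types.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Tuple, Union

import numpy as np
import pandas as pd

logger = logging.getLogger("landfillch4")

__all__ = [
    "Unit",
    "AnnualSeries",
    "WasteRecord",
    "SocioeconProjection",
    "ValidationError",
    "UnitMismatchError",
    "ConfigurationError",
    "YearRangeError",
    "FixtureIntegrityError",
    "read_series_csv",
    "write_series_csv",
    "convert_series",
    "TONNES_PER_GG",
]

#: 1 Gg (gigagram) = 1000 metric tonnes = 1 kt.
TONNES_PER_GG = 1000.0


class LandfillCH4Error(Exception):
    """Base class for all package errors."""


class ValidationError(LandfillCH4Error, ValueError):
    """Input data violates a documented invariant."""


class UnitMismatchError(ValidationError):
    """Arithmetic attempted between series carrying different units."""


class ConfigurationError(LandfillCH4Error):
    """Run configuration or parameter set is incomplete or unrecognized."""


class YearRangeError(LandfillCH4Error, ValueError):
    """Requested year falls outside the defined range (no extrapolation)."""


class FixtureIntegrityError(LandfillCH4Error):
    """A bundled data table does not match its printed source values."""


class Unit(str, Enum):
    """Units a series may carry; fixed for the series' lifetime."""

    GG_CH4 = "Gg_CH4"
    KT_CO2E = "kt_CO2e"
    TONS_PER_YEAR = "tons_per_year"
    PERSONS = "persons"
    USD = "USD"
    USD_PER_PERSON = "USD_per_person"

    @classmethod
    def parse(cls, label: Union[str, "Unit"]) -> "Unit":
        if isinstance(label, cls):
            return label
        try:
            return cls(label)
        except ValueError:
            valid = ", ".join(u.value for u in cls)
            raise ConfigurationError(
                f"unknown unit {label!r}; expected one of: {valid}"
            ) from None


class AnnualSeries:
    """Immutable year-indexed series of non-negative quantities.

    Years are strictly increasing Gregorian calendar labels, interpreted as
    end-of-year annual totals. Arithmetic between two series requires the
    same unit and the same year grid; subtraction that would drive a value
    negative is rejected rather than silently clamped (the scenario engine
    applies its non-negativity clamp explicitly).
    """

    __slots__ = ("_unit", "_years", "_values")

    def __init__(
        self,
        unit: Union[str, Unit],
        values: Union[Mapping[int, float], Iterable[Tuple[int, float]]],
    ) -> None:
        self._unit = Unit.parse(unit)
        pairs = list(values.items()) if isinstance(values, Mapping) else list(values)
        if not pairs:
            raise ValidationError("an AnnualSeries needs at least one (year, value)")
        pairs.sort(key=lambda p: p[0])
        years = np.array([int(y) for y, _ in pairs], dtype=np.int64)
        vals = np.array([float(v) for _, v in pairs], dtype=np.float64)
        if len(np.unique(years)) != len(years):
            dup = int(years[np.where(np.diff(years) == 0)[0][0]])
            raise ValidationError(f"duplicate year {dup} in series")
        if np.any(~np.isfinite(vals)) or np.any(vals < 0):
            bad = int(years[np.where(~(np.isfinite(vals) & (vals >= 0)))[0][0]])
            raise ValidationError(f"non-finite or negative value at year {bad}")
        self._years = years
        self._values = vals
        self._years.setflags(write=False)
        self._values.setflags(write=False)

    # -- accessors ---------------------------------------------------------

    @property
    def unit(self) -> Unit:
        return self._unit

    @property
    def years(self) -> Tuple[int, ...]:
        return tuple(int(y) for y in self._years)

    @property
    def values(self) -> Tuple[float, ...]:
        return tuple(float(v) for v in self._values)

    def __len__(self) -> int:
        return len(self._years)

    def __iter__(self) -> Iterator[Tuple[int, float]]:
        return iter(zip(self.years, self.values))

    def __contains__(self, year: int) -> bool:
        i = bisect_left(self._years, year)
        return i < len(self._years) and self._years[i] == year

    def __getitem__(self, year: int) -> float:
        i = bisect_left(self._years, year)
        if i == len(self._years) or self._years[i] != year:
            raise KeyError(f"year {year} not in series ({self.first_year}-{self.last_year})")
        return float(self._values[i])

    def get(self, year: int, default: float | None = None) -> float | None:
        return self[year] if year in self else default

    @property
    def first_year(self) -> int:
        return int(self._years[0])

    @property
    def last_year(self) -> int:
        return int(self._years[-1])

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.years, self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "value": self.values})

    # -- arithmetic --------------------------------------------------------

    def _check_compatible(self, other: "AnnualSeries", op: str) -> None:
        if not isinstance(other, AnnualSeries):
            raise TypeError(f"cannot {op} AnnualSeries and {type(other).__name__}")
        if other.unit is not self.unit:
            raise UnitMismatchError(
                f"cannot {op} series in {self.unit.value} and {other.unit.value}"
            )
        if not np.array_equal(self._years, other._years):
            raise ValidationError(f"cannot {op} series on different year grids")

    def __add__(self, other: "AnnualSeries") -> "AnnualSeries":
        self._check_compatible(other, "add")
        return AnnualSeries(self.unit, zip(self.years, self._values + other._values))

    def __sub__(self, other: "AnnualSeries") -> "AnnualSeries":
        self._check_compatible(other, "subtract")
        return AnnualSeries(self.unit, zip(self.years, self._values - other._values))

    def __mul__(self, scalar: float) -> "AnnualSeries":
        if not np.isscalar(scalar):
            raise TypeError("AnnualSeries can only be scaled by a scalar")
        return AnnualSeries(self.unit, zip(self.years, self._values * float(scalar)))

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AnnualSeries)
            and self.unit is other.unit
            and np.array_equal(self._years, other._years)
            and np.array_equal(self._values, other._values)
        )

    def __hash__(self) -> int:
        return hash((self._unit, self._years.tobytes(), self._values.tobytes()))

    def __repr__(self) -> str:
        return (
            f"AnnualSeries({self.unit.value}, {self.first_year}-{self.last_year}, "
            f"n={len(self)})"
        )


def convert_series(series: AnnualSeries, unit: Union[str, Unit]) -> AnnualSeries:
    """Convert between the mass units Gg CH4/yr and tons CH4/yr (1 Gg = 1000 t).

    Any other unit change is rejected: the remaining units are not
    dimensionally interchangeable by a pure scale factor.
    """
    target = Unit.parse(unit)
    if target is series.unit:
        return series
    scale = {
        (Unit.GG_CH4, Unit.TONS_PER_YEAR): TONNES_PER_GG,
        (Unit.TONS_PER_YEAR, Unit.GG_CH4): 1.0 / TONNES_PER_GG,
    }.get((series.unit, target))
    if scale is None:
        raise UnitMismatchError(
            f"no conversion from {series.unit.value} to {target.value}"
        )
    return AnnualSeries(target, zip(series.years, (v * scale for v in series.values)))


@dataclass(frozen=True)
class WasteRecord:
    """Annual municipal solid waste landfilled at one site, in Gg/yr."""

    site_id: str
    year: int
    msw_mass: float  # Gg/yr (thousand tonnes/yr)

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValidationError("site_id must be non-empty")
        if not np.isfinite(self.msw_mass) or self.msw_mass < 0:
            raise ValidationError(
                f"msw_mass must be >= 0 ({self.site_id}, {self.year}: {self.msw_mass})"
            )


@dataclass(frozen=True)
class SocioeconProjection:
    """One projection year of demographic, economic and health-risk context."""

    year: int
    population: float  # millions of persons
    population_growth: float  # %/yr
    gdp: float  # billion USD
    gdp_growth: float  # %/yr
    average_income: float  # USD/person/yr
    ozone_rr: float  # relative risk of respiratory disease from ozone

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValidationError(f"population must be > 0 (year {self.year})")
        if self.gdp <= 0:
            raise ValidationError(f"gdp must be > 0 (year {self.year})")
        if self.ozone_rr < 1:
            raise ValidationError(f"ozone_rr must be >= 1 (year {self.year})")


# -- series CSV IO ---------------------------------------------------------


def read_series_csv(path: Union[str, Path], unit: Union[str, Unit]) -> AnnualSeries:
    """Read an AnnualSeries from a two-column ``year,value`` CSV.

    Raises :class:`ValidationError` (with the offending row number) on
    negative values or duplicate years, and :class:`ConfigurationError` on an
    unrecognized unit label.
    """
    unit = Unit.parse(unit)
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty series file") from None
    missing = {"year", "value"} - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    if frame.empty:
        raise ValidationError(f"{path}: no data rows")
    for offset, row in enumerate(frame.itertuples(index=False), start=2):
        value = float(row.value)
        if not np.isfinite(value) or value < 0:
            raise ValidationError(f"{path}: negative or non-finite value at row {offset}")
    years = frame["year"].astype(int)
    if years.duplicated().any():
        dup_row = int(years.index[years.duplicated()][0]) + 2
        raise ValidationError(f"{path}: duplicate year at row {dup_row}")
    return AnnualSeries(unit, zip(years, frame["value"].astype(float)))


def write_series_csv(series: AnnualSeries, path: Union[str, Path]) -> Path:
    """Write a series as ``year,value`` CSV (full float precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = series.to_frame()
    frame["value"] = [repr(v) for v in series.values]  # round-trip exact
    frame.to_csv(path, index=False)
    return path
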