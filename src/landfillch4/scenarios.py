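"""Mitigation-scenario wedge accounting and strategy comparison.

An :class:`Intervention` is a named mitigation wedge subtracted from a
baseline emission trajectory. Wedges come in two modes:

* ``absolute`` — the schedule gives kt CO2e/yr removed at milestone years;
  between milestones the reduction is linearly interpolated, and it holds
  its last value after the final milestone.
* ``fraction_of_baseline`` — the schedule gives a dimensionless fraction of
  the baseline removed; between milestones the *fraction* is held constant
  (step-wise), so the wedge scales with the growing baseline.

Both evaluate to a reduction in the baseline's unit at a given year; the net
trajectory is the baseline minus the summed reductions, clamped at zero.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Mapping, Sequence, Tuple, Union

import pandas as pd

from .core import AnnualSeries, ValidationError, YearRangeError
from .emissions import interpolate_baseline

__all__ = [
    "Phase",
    "WedgeMode",
    "Intervention",
    "ScenarioResult",
    "wedge_reduction",
    "apply_interventions",
    "build_scenario",
    "percent_reduction",
    "ledger_subtotal",
    "compare_strategies",
]


class Phase(str, Enum):
    SHORT_TERM = "short_term"
    MID_TERM = "mid_term"
    LONG_TERM = "long_term"


class WedgeMode(str, Enum):
    ABSOLUTE = "absolute"
    FRACTION_OF_BASELINE = "fraction_of_baseline"


@dataclass(frozen=True)
class Intervention:
    """A named mitigation wedge with a milestone reduction schedule.

    ``schedule`` maps milestone year -> reduction: kt CO2e/yr for absolute
    wedges, a fraction of baseline (<= 1) for fractional ones.
    ``counted_in_subtotal`` mirrors the source ledger, where one short-term
    item is listed but excluded from its phase subtotal.
    """

    id: str
    title: str
    phase: Phase
    mode: WedgeMode
    schedule: Mapping[int, float]
    counted_in_subtotal: bool = True

    def __post_init__(self) -> None:
        if not self.schedule:
            raise ValidationError(f"intervention {self.id!r}: empty schedule")
        object.__setattr__(self, "phase", Phase(self.phase))
        object.__setattr__(self, "mode", WedgeMode(self.mode))
        sched = {int(y): float(v) for y, v in self.schedule.items()}
        for year, value in sched.items():
            if value < 0:
                raise ValidationError(
                    f"intervention {self.id!r}: negative reduction at {year}"
                )
            if self.mode is WedgeMode.FRACTION_OF_BASELINE and value > 1:
                raise ValidationError(
                    f"intervention {self.id!r}: fraction {value} > 1 at {year}"
                )
        object.__setattr__(self, "schedule", dict(sorted(sched.items())))

    @property
    def milestones(self) -> Tuple[int, ...]:
        return tuple(self.schedule)


@dataclass(frozen=True)
class ScenarioResult:
    """Baseline and net emission trajectories plus the per-wedge reductions."""

    baseline: AnnualSeries
    net: AnnualSeries
    per_intervention_reduction: Dict[str, AnnualSeries]


def wedge_reduction(
    intervention: Intervention,
    baseline_value: float,
    year: int,
) -> float:
    """Reduction (baseline units) delivered by one wedge at ``year``."""
    sched = intervention.schedule
    years = list(sched)
    if year < years[0]:
        raise YearRangeError(
            f"intervention {intervention.id!r} starts at {years[0]}, "
            f"year {year} requested"
        )
    i = bisect_right(years, year)
    if intervention.mode is WedgeMode.FRACTION_OF_BASELINE:
        # step-wise constant fraction: latest milestone at or before `year`
        return sched[years[i - 1]] * baseline_value
    if i == len(years):
        return sched[years[-1]]  # hold last absolute value
    y0, y1 = years[i - 1], years[i]
    if y0 == year:
        return sched[y0]
    t = (year - y0) / (y1 - y0)
    return sched[y0] + t * (sched[y1] - sched[y0])


def apply_interventions(
    baseline: Union[AnnualSeries, float],
    interventions: Iterable[Intervention],
    year: int,
) -> Tuple[float, Dict[str, float]]:
    """Net emissions and per-wedge reductions at ``year``.

    ``baseline`` may be a scalar value at that year or an anchored series
    (interpolated geometrically). The net is floored at zero; the unclamped
    identity ``baseline - net == sum(reductions)`` holds whenever the clamp
    does not trigger.
    """
    if isinstance(baseline, AnnualSeries):
        base_value = interpolate_baseline(baseline, year)
    else:
        base_value = float(baseline)
    reductions = {
        iv.id: wedge_reduction(iv, base_value, year) for iv in interventions
    }
    net = max(0.0, base_value - sum(reductions.values()))
    return net, reductions


def build_scenario(
    baseline_anchors: AnnualSeries,
    interventions: Sequence[Intervention],
    years: Iterable[int] | None = None,
    mode: str = "geometric",
) -> ScenarioResult:
    """Evaluate a wedge portfolio over a year range against anchored baseline.

    Years before a wedge's first milestone contribute zero reduction for
    that wedge (the project has not started), rather than raising.
    """
    if years is None:
        years = range(baseline_anchors.first_year, baseline_anchors.last_year + 1)
    years = [int(y) for y in years]
    base = {y: interpolate_baseline(baseline_anchors, y, mode) for y in years}
    per_iv: Dict[str, Dict[int, float]] = {iv.id: {} for iv in interventions}
    net: Dict[int, float] = {}
    for y in years:
        total = 0.0
        for iv in interventions:
            red = 0.0 if y < iv.milestones[0] else wedge_reduction(iv, base[y], y)
            per_iv[iv.id][y] = red
            total += red
        net[y] = max(0.0, base[y] - total)
    unit = baseline_anchors.unit
    return ScenarioResult(
        baseline=AnnualSeries(unit, base),
        net=AnnualSeries(unit, net),
        per_intervention_reduction={
            k: AnnualSeries(unit, v) for k, v in per_iv.items()
        },
    )


def percent_reduction(baseline_value: float, net_value: float) -> float:
    """Percent reduction of net relative to baseline, full precision.

    Display convention rounds to the nearest integer (``round(x)``).
    """
    if baseline_value <= 0:
        raise ValidationError(f"baseline must be > 0, got {baseline_value}")
    if net_value < 0:
        raise ValidationError(f"net must be >= 0, got {net_value}")
    return 100.0 * (baseline_value - net_value) / baseline_value


def ledger_subtotal(
    interventions: Iterable[Intervention],
    phase: Union[str, Phase],
    milestone_year: int = 2050,
) -> float:
    """Sum of ledger reductions at ``milestone_year`` for one phase.

    Only wedges flagged ``counted_in_subtotal`` contribute, matching the
    source ledger's exclusion of one listed short-term item. An empty phase
    sums to 0.
    """
    phase = Phase(phase)
    return sum(
        iv.schedule.get(milestone_year, 0.0)
        for iv in interventions
        if iv.phase is phase and iv.counted_in_subtotal
    )


def compare_strategies(
    series_set: Mapping[str, AnnualSeries],
    baseline_name: str,
    year: int,
) -> pd.DataFrame:
    """Tabulate each strategy's emissions at ``year`` against the baseline.

    Returns one row per non-baseline strategy with columns ``strategy``,
    ``emissions``, ``percent_reduction`` (full precision) and
    ``percent_display`` (nearest integer). All series must share unit and
    year grid.
    """
    if baseline_name not in series_set:
        raise ValidationError(f"baseline {baseline_name!r} not among strategies")
    base = series_set[baseline_name]
    for name, series in series_set.items():
        if series.unit is not base.unit:
            raise ValidationError(
                f"strategy {name!r} unit {series.unit.value} differs from "
                f"baseline unit {base.unit.value}"
            )
        if series.years != base.years:
            raise ValidationError(f"strategy {name!r} is on a different year grid")
    rows = []
    for name, series in series_set.items():
        if name == baseline_name:
            continue
        pct = percent_reduction(base[year], series[year])
        rows.append(
            {
                "strategy": name,
                "emissions": series[year],
                "percent_reduction": pct,
                "percent_display": int(round(pct)),
            }
        )
    return pd.DataFrame(rows)
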