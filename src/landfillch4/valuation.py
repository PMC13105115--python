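"""Value-of-statistical-life construction and mortality monetization.

A VSL is willingness-to-pay for a small mortality-risk reduction divided by
that risk reduction. Reference VSLs (typically from high-income settings)
are transferred to a target economy with an income-elasticity adjustment:

    VSL_target = VSL_reference * (income_target / income_reference)^elasticity

Mortality cost in a year is attributable deaths times the VSL in force.
The study default for Jordan is $1.3M (2022), the worldwide meta-analytic
average; elasticity defaults to 0.85.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import pandas as pd

from .core import ValidationError
from .health import HealthBurden

__all__ = [
    "VSLSpec",
    "DamageEstimate",
    "DEFAULT_JORDAN_VSL",
    "DEFAULT_ELASTICITY",
    "vsl_from_wtp",
    "adjust_vsl",
    "implied_income_ratio",
    "mortality_cost",
    "damage_frame",
]

#: Jordan VSL adopted for 2022, USD.
DEFAULT_JORDAN_VSL = 1.3e6
#: Default income elasticity of the VSL.
DEFAULT_ELASTICITY = 0.85


@dataclass(frozen=True)
class VSLSpec:
    """Benefit-transfer inputs: reference VSL, incomes and elasticity."""

    vsl_reference: float  # USD
    income_reference: float  # USD/person/yr
    income_target: float  # USD/person/yr
    elasticity: float = DEFAULT_ELASTICITY

    def __post_init__(self) -> None:
        if self.vsl_reference <= 0:
            raise ValidationError(f"vsl_reference must be > 0, got {self.vsl_reference}")
        if self.income_reference <= 0 or self.income_target <= 0:
            raise ValidationError("incomes must be > 0")
        if self.elasticity < 0:
            raise ValidationError(f"elasticity must be >= 0, got {self.elasticity}")


@dataclass(frozen=True)
class DamageEstimate:
    """Monetized mortality for one year: deaths x VSL."""

    year: int
    deaths: float
    vsl_used: float  # USD
    mortality_cost: float  # USD/yr


def vsl_from_wtp(wtp: float, risk_reduction: float) -> float:
    """VSL from a willingness-to-pay for a small risk reduction.

    E.g. $300 WTP for a 1-in-10,000 reduction implies a $3M VSL.
    """
    if not 0 < risk_reduction < 1:
        raise ValidationError(
            f"risk_reduction must be strictly between 0 and 1, got {risk_reduction}"
        )
    if wtp < 0:
        raise ValidationError(f"wtp must be >= 0, got {wtp}")
    return wtp / risk_reduction


def adjust_vsl(spec: VSLSpec) -> float:
    """Income-elasticity benefit transfer of a reference VSL."""
    return spec.vsl_reference * (spec.income_target / spec.income_reference) ** spec.elasticity


def implied_income_ratio(
    vsl_reference: float,
    vsl_target: float,
    elasticity: float = DEFAULT_ELASTICITY,
) -> float:
    """Diagnostic: the income ratio a transfer must have assumed.

    Inverts the transfer: ratio = (VSL_target / VSL_reference)^(1/elasticity).
    Useful when a published adjustment omits its reference income (e.g. the
    $7.2M -> $1.16M transfer implies a ratio of about 0.117).
    """
    if vsl_reference <= 0 or vsl_target <= 0:
        raise ValidationError("VSLs must be > 0")
    if elasticity <= 0:
        raise ValidationError(f"elasticity must be > 0 to invert, got {elasticity}")
    return (vsl_target / vsl_reference) ** (1.0 / elasticity)


def mortality_cost(
    burdens: Sequence[HealthBurden],
    vsl: float,
) -> List[DamageEstimate]:
    """Monetize a burden series at a constant VSL."""
    if vsl <= 0:
        raise ValidationError(f"vsl must be > 0, got {vsl}")
    return [
        DamageEstimate(
            year=b.year,
            deaths=b.deaths,
            vsl_used=vsl,
            mortality_cost=b.deaths * vsl,
        )
        for b in burdens
    ]


def damage_frame(damages: Sequence[DamageEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "year": [d.year for d in damages],
            "deaths": [d.deaths for d in damages],
            "vsl_usd": [d.vsl_used for d in damages],
            "mortality_cost_usd": [d.mortality_cost for d in damages],
        }
    )
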