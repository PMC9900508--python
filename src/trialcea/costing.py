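"""Costing of TIC-P resource-use items under nested analytic perspectives.

Resource use is recorded over a 4-week recall window ("how many days of
sick leave did you have in the past 4 weeks?"), extrapolated to the full
12-week period between assessments, priced in Swedish crowns (SEK) and
converted to US dollars at a purchasing-power-parity rate.

Cost categories are additive and the perspectives nest:

* clinic          = treatment provision only (therapist time)
* health care     = clinic + other health-care visits + medication
* societal        = health care + sick leave + domestic cutback + unemployment

Productivity losses use the human-capital approach: lost workdays are
valued at the gross hourly wage.  Unemployment is a fixed per-period
amount (80% of a monthly gross salary), *not* recall-extrapolated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Perspective",
    "TariffTable",
    "CostBreakdown",
    "extrapolate_recall",
    "convert_sek_to_usd",
    "productivity_loss",
    "compute_cost_breakdown",
    "assemble_perspective",
    "cost_table",
    "COST_CATEGORIES",
    "RESOURCE_ITEMS",
]

#: money categories of a CostBreakdown, in reporting order
COST_CATEGORIES = (
    "treatment_provision",
    "other_health_care",
    "medication",
    "sick_leave",
    "domestic_cutback",
    "unemployment",
)

#: resource-use columns expected on a participant record
RESOURCE_ITEMS = (
    "primary_care_visits",
    "specialist_visits",
    "psychiatric_visits",
    "medication_units",
    "sick_leave_days",
    "domestic_cutback_hours",
    "unemployed",
)

_VISIT_ITEM_TO_TARIFF = {
    "primary_care_visits": "primary_care_visit",
    "specialist_visits": "specialist_visit",
    "psychiatric_visits": "psychiatric_visit",
}


class Perspective(str, enum.Enum):
    """Which cost categories are counted."""

    CLINIC = "clinic"
    HEALTH_CARE = "health_care"
    SOCIETAL = "societal"
    SOCIETAL_EXCL_UNEMPLOYMENT = "societal_excl_unemployment"


@dataclass
class TariffTable:
    """Unit costs and scalar rates used to money-value resource use.

    Defaults reflect 2014 Swedish conditions: a gross hourly wage of
    188 SEK, domestic work valued at EUR 14/h, unemployment fixed at
    24 000 SEK per 12-week period, and a purchasing-power parity of
    6.861 SEK per USD.  Visit/medication unit costs are editable
    placeholder tariffs in the style of the official Swedish listings.
    """

    unit_cost_sek: dict[str, float] = field(
        default_factory=lambda: {
            "primary_care_visit": 1700.0,
            "specialist_visit": 1500.0,
            "psychiatric_visit": 2000.0,
            "medication_unit": 300.0,
        }
    )
    hourly_wage_sek: float = 188.0
    domestic_hourly_eur: float = 14.0
    eur_to_sek: float = 9.10
    unemployment_fixed_sek: float = 24000.0
    sek_per_usd: float = 6.861
    hours_per_workday: float = 8.0
    treatment_cost_usd: dict[str, float] = field(
        default_factory=lambda: {"intervention": 946.0, "control": 461.0}
    )
    recall_weeks: float = 4.0
    period_weeks: float = 12.0

    def __post_init__(self) -> None:
        scalars = {
            "hourly_wage_sek": self.hourly_wage_sek,
            "domestic_hourly_eur": self.domestic_hourly_eur,
            "eur_to_sek": self.eur_to_sek,
            "unemployment_fixed_sek": self.unemployment_fixed_sek,
            "sek_per_usd": self.sek_per_usd,
            "hours_per_workday": self.hours_per_workday,
            "recall_weeks": self.recall_weeks,
            "period_weeks": self.period_weeks,
        }
        for name, value in scalars.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        for item, cost in self.unit_cost_sek.items():
            if cost <= 0:
                raise ValueError(f"unit cost for {item!r} must be positive, got {cost}")

    # -- per-unit USD prices over the full assessment period -------------
    def usd_per_unit(self, item: str) -> float:
        """Full-period USD cost of one recall-window unit of *item*.

        Applies recall extrapolation then currency conversion; the
        unemployment flag is priced as a fixed per-period amount with no
        extrapolation.
        """
        if item in _VISIT_ITEM_TO_TARIFF:
            sek = self.unit_cost_sek[_VISIT_ITEM_TO_TARIFF[item]]
        elif item == "medication_units":
            sek = self.unit_cost_sek["medication_unit"]
        elif item == "sick_leave_days":
            sek = self.hours_per_workday * self.hourly_wage_sek
        elif item == "domestic_cutback_hours":
            sek = self.domestic_hourly_eur * self.eur_to_sek
        elif item == "unemployed":
            return convert_sek_to_usd(self.unemployment_fixed_sek, self.sek_per_usd)
        else:
            raise KeyError(f"unknown resource item {item!r}")
        extrapolated = extrapolate_recall(sek, self.recall_weeks, self.period_weeks)
        return convert_sek_to_usd(extrapolated, self.sek_per_usd)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "TariffTable":
        return cls(**dict(d))

    @classmethod
    def from_csv(cls, path, **scalars) -> "TariffTable":
        """Load visit/medication unit costs from a two-column CSV
        (``item,unit_cost_sek``); scalar rates may be overridden by keyword."""
        df = pd.read_csv(path)
        unit = dict(zip(df["item"], df["unit_cost_sek"].astype(float)))
        return cls(unit_cost_sek=unit, **scalars)


@dataclass
class CostBreakdown:
    """Per-category USD amounts for one participant x timepoint."""

    treatment_provision: float = 0.0
    other_health_care: float = 0.0
    medication: float = 0.0
    sick_leave: float = 0.0
    domestic_cutback: float = 0.0
    unemployment: float = 0.0

    def __post_init__(self) -> None:
        for cat in COST_CATEGORIES:
            if getattr(self, cat) < 0:
                raise ValueError(f"cost category {cat!r} must be nonnegative")

    @property
    def clinic(self) -> float:
        return self.treatment_provision

    @property
    def health_care(self) -> float:
        return self.clinic + self.other_health_care + self.medication

    @property
    def societal(self) -> float:
        return (
            self.health_care + self.sick_leave + self.domestic_cutback + self.unemployment
        )

    @property
    def societal_excl_unemployment(self) -> float:
        return self.societal - self.unemployment

    def total(self, perspective: Perspective | str) -> float:
        return assemble_perspective(self, perspective)


def extrapolate_recall(
    amount: float, recall_weeks: float = 4, period_weeks: float = 12
) -> float:
    """Scale a recall-window amount to the full between-assessment period.

    With the default 4-week recall and 12-week period this multiplies
    by 3.  Linear, so it commutes with summation over categories.
    """
    if recall_weeks <= 0:
        raise ValueError(f"recall_weeks must be positive, got {recall_weeks}")
    return amount * period_weeks / recall_weeks


def convert_sek_to_usd(amount_sek: float, rate: float = 6.861) -> float:
    """Convert SEK to USD at a purchasing-power-parity rate (SEK per USD)."""
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    return amount_sek / rate


def productivity_loss(sick_days: float, tariff: TariffTable | None = None) -> float:
    """Human-capital value of lost workdays, in SEK.

    One sick day is ``hours_per_workday`` hours at the gross hourly wage.
    """
    if sick_days < 0:
        raise ValueError(f"sick_days must be nonnegative, got {sick_days}")
    tariff = tariff or TariffTable()
    return sick_days * tariff.hours_per_workday * tariff.hourly_wage_sek


def compute_cost_breakdown(
    record: Mapping,
    tariff: TariffTable | None = None,
    *,
    arm: str | None = None,
    timepoint: str | None = None,
    treatment_period: str = "post",
) -> CostBreakdown:
    """Money-value one participant x timepoint record.

    *record* maps resource-item names (see :data:`RESOURCE_ITEMS`) to
    nonnegative counts/hours; ``unemployed`` is a 0/1 flag.  Visit,
    medication, sick-leave and domestic amounts are recall-extrapolated
    to the full period and converted to USD; the unemployment amount is
    a fixed per-period sum.  Treatment provision is added once, at the
    *treatment_period* timepoint, at the arm's fixed cost.

    Raises ``KeyError`` for unknown item keys and ``ValueError`` for
    negative counts or missing values.
    """
    tariff = tariff or TariffTable()
    arm = arm if arm is not None else record.get("arm")
    timepoint = timepoint if timepoint is not None else record.get("timepoint")

    amounts = {}
    for item in RESOURCE_ITEMS:
        value = record.get(item, 0.0)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(
                f"missing value for {item!r}; handle missingness upstream"
            )
        if value < 0:
            raise ValueError(f"negative count for {item!r}: {value}")
        amounts[item] = float(value)
    unknown = set(record) - set(RESOURCE_ITEMS) - {"arm", "timepoint", "participant_id"}
    if unknown:
        raise KeyError(f"unknown resource item(s): {sorted(unknown)}")

    other_health_care = sum(
        amounts[item] * tariff.usd_per_unit(item) for item in _VISIT_ITEM_TO_TARIFF
    )
    medication = amounts["medication_units"] * tariff.usd_per_unit("medication_units")
    sick_leave = amounts["sick_leave_days"] * tariff.usd_per_unit("sick_leave_days")
    domestic = amounts["domestic_cutback_hours"] * tariff.usd_per_unit(
        "domestic_cutback_hours"
    )
    unemployment = amounts["unemployed"] * tariff.usd_per_unit("unemployed")

    treatment = 0.0
    if timepoint == treatment_period and arm is not None:
        treatment = float(tariff.treatment_cost_usd[arm])

    return CostBreakdown(
        treatment_provision=treatment,
        other_health_care=other_health_care,
        medication=medication,
        sick_leave=sick_leave,
        domestic_cutback=domestic,
        unemployment=unemployment,
    )


def assemble_perspective(
    breakdown: CostBreakdown, perspective: Perspective | str
) -> float:
    """Total cost of a breakdown under one perspective (categories are additive)."""
    p = Perspective(perspective)
    if p is Perspective.CLINIC:
        return breakdown.clinic
    if p is Perspective.HEALTH_CARE:
        return breakdown.health_care
    if p is Perspective.SOCIETAL:
        return breakdown.societal
    if p is Perspective.SOCIETAL_EXCL_UNEMPLOYMENT:
        return breakdown.societal_excl_unemployment
    raise ValueError(f"unknown perspective {perspective!r}")  # pragma: no cover


def cost_table(
    records: pd.DataFrame,
    tariff: TariffTable | None = None,
    *,
    treatment_period: str = "post",
) -> pd.DataFrame:
    """Vectorised costing of a participant x timepoint table.

    Returns one row per input row with the six cost categories and the
    four perspective totals in USD.  Rows with missing resource items
    (a skipped TIC-P) get NaN in every affected column; missingness is
    resolved downstream by likelihood-based model fitting, never imputed
    here.
    """
    tariff = tariff or TariffTable()
    out = records[["participant_id", "arm", "timepoint"]].copy()

    items = records[list(RESOURCE_ITEMS)].astype(float)
    if (items.to_numpy() < 0).any():
        raise ValueError("negative resource counts in input table")
    missing = items.isna().any(axis=1)

    out["other_health_care"] = sum(
        items[item] * tariff.usd_per_unit(item) for item in _VISIT_ITEM_TO_TARIFF
    )
    out["medication"] = items["medication_units"] * tariff.usd_per_unit(
        "medication_units"
    )
    out["sick_leave"] = items["sick_leave_days"] * tariff.usd_per_unit(
        "sick_leave_days"
    )
    out["domestic_cutback"] = items["domestic_cutback_hours"] * tariff.usd_per_unit(
        "domestic_cutback_hours"
    )
    out["unemployment"] = items["unemployed"] * tariff.usd_per_unit("unemployed")
    out["treatment_provision"] = np.where(
        records["timepoint"].to_numpy() == treatment_period,
        records["arm"].map(tariff.treatment_cost_usd).to_numpy(float),
        0.0,
    )

    out["clinic"] = out["treatment_provision"]
    out["health_care"] = out["clinic"] + out["other_health_care"] + out["medication"]
    out["societal"] = (
        out["health_care"]
        + out["sick_leave"]
        + out["domestic_cutback"]
        + out["unemployment"]
    )
    out["societal_excl_unemployment"] = out["societal"] - out["unemployment"]

    money_cols = list(COST_CATEGORIES) + [p.value for p in Perspective]
    out.loc[missing, [c for c in money_cols if c != "treatment_provision"]] = np.nan
    # perspective totals involving missing categories are undefined
    out.loc[missing, ["clinic"]] = out.loc[missing, "treatment_provision"]
    out.loc[missing, ["health_care", "societal", "societal_excl_unemployment"]] = np.nan
    return out
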