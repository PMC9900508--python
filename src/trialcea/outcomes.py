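"""Effect measures: EQ-5D utility index and incremental QALY contrasts.

The EQ-5D describes health on five domains (mobility, self-care,
pain/discomfort, daily activities, anxiety/depression).  A value set
maps a domain-level profile to a single utility index anchored at
1 (full health) and 0 (dead); some national value sets allow states
worse than dead.  The incremental QALY effect is operationalised as the
difference-in-differences of index values: the arm contrast of change
from pre-treatment, i.e. the group x time interaction of the mixed
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import inference

__all__ = ["EQ5D_DOMAINS", "ValueSet", "eq5d_index", "qaly_effect", "qaly_auc"]

EQ5D_DOMAINS = (
    "mobility",
    "self_care",
    "pain_discomfort",
    "daily_activities",
    "anxiety_depression",
)


@dataclass
class ValueSet:
    """Decrement table translating an EQ-5D profile into a utility index.

    ``decrements[(domain, level)]`` is the utility lost relative to full
    health; the full-health profile (all domains at level 1) must map to
    ``full_health`` = 1.0.  Real national value sets (UK TTO, Swedish,
    Danish, ...) can be loaded from CSV; :meth:`toy` builds a simple
    synthetic three-level set for testing and examples.
    """

    decrements: dict[tuple[str, int], float] = field(default_factory=dict)
    full_health: float = 1.0
    floor: float | None = 0.0  # clamp; None accepts states worse than dead

    def __post_init__(self) -> None:
        for (domain, level), dec in self.decrements.items():
            if domain not in EQ5D_DOMAINS:
                raise KeyError(f"unknown EQ-5D domain {domain!r}")
            if level == 1 and dec != 0.0:
                raise ValueError("level 1 must carry zero decrement (full health)")

    @classmethod
    def toy(cls, per_level: float = 0.1, levels: int = 3) -> "ValueSet":
        """Uniform synthetic set: each level above 1 costs `per_level` utility."""
        dec = {
            (d, lv): per_level * (lv - 1)
            for d in EQ5D_DOMAINS
            for lv in range(1, levels + 1)
        }
        return cls(decrements=dec)

    @classmethod
    def from_csv(cls, path, *, floor: float | None = None) -> "ValueSet":
        """Load a ``domain,level,decrement`` CSV."""
        df = pd.read_csv(path)
        dec = {
            (row.domain, int(row.level)): float(row.decrement)
            for row in df.itertuples()
        }
        return cls(decrements=dec, floor=floor)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"domain": d, "level": lv, "decrement": dec}
                for (d, lv), dec in sorted(self.decrements.items())
            ]
        )


def eq5d_index(levels, value_set: ValueSet | None = None) -> float:
    """Utility index of an EQ-5D profile: full health minus summed decrements.

    *levels* is a sequence of five domain levels in :data:`EQ5D_DOMAINS`
    order, or a mapping domain -> level.  Deterministic table lookup;
    raises ``KeyError`` for a level outside the value set.
    """
    value_set = value_set or ValueSet.toy()
    if isinstance(levels, dict):
        profile = [(d, levels[d]) for d in EQ5D_DOMAINS]
    else:
        if len(levels) != len(EQ5D_DOMAINS):
            raise ValueError(f"expected {len(EQ5D_DOMAINS)} levels, got {len(levels)}")
        profile = list(zip(EQ5D_DOMAINS, levels))
    total_dec = 0.0
    for domain, level in profile:
        key = (domain, int(level))
        if key not in value_set.decrements:
            raise KeyError(f"no decrement for {domain!r} level {level}")
        total_dec += value_set.decrements[key]
    index = value_set.full_health - total_dec
    if value_set.floor is not None:
        index = max(index, value_set.floor)
    return index


def qaly_effect(fit: "inference.MixedModelFit", timepoint: str) -> "inference.Contrast":
    """Incremental QALY at *timepoint*: the arm contrast of EQ-5D change
    from pre-treatment (difference-in-differences), read off the fitted
    group x time interaction.  Undefined at pre-treatment."""
    return inference.did_contrast(fit, timepoint)


def qaly_auc(
    cell_means: pd.DataFrame, *, weeks_per_interval: float = 12.0
) -> pd.Series:
    """Time-integrated QALYs per arm (trapezoid over timepoints), in years.

    Optional alternative to the difference-in-differences convention;
    expects a ``arm x timepoint`` table of EQ-5D means with timepoints
    in temporal order.
    """
    years = weeks_per_interval / 52.0
    out = {}
    for arm, row in cell_means.iterrows():
        vals = row.to_numpy(float)
        out[arm] = float(sum((vals[i] + vals[i + 1]) / 2 * years for i in range(len(vals) - 1)))
    return pd.Series(out, name="qaly_auc")
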