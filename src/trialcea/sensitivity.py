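"""Robustness checks: complete-case analysis and exclusion of
unemployment costs.

Complete-case filtering is defined per analysis (per outcome/cost
column), not as one global listwise deletion, because completion rates
differ by instrument.  The unemployment exclusion re-runs the pipeline
under the ``societal_excl_unemployment`` perspective; clinic and
health-care results are untouched by construction since unemployment is
a societal-only category.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["SensitivitySpec", "complete_case_filter", "run_excluding_unemployment"]

SENSITIVITY_MODES = ("complete_case", "exclude_unemployment")


@dataclass
class SensitivitySpec:
    mode: str
    base_label: str = "base"

    def __post_init__(self) -> None:
        if self.mode not in SENSITIVITY_MODES:
            raise ValueError(
                f"mode must be one of {SENSITIVITY_MODES}, got {self.mode!r}"
            )


def complete_case_filter(
    table: pd.DataFrame,
    columns,
    *,
    timepoints=None,
) -> pd.DataFrame:
    """Retain only participants with no missing value in *columns* at any
    analysed timepoint.

    *timepoints* defaults to every timepoint in the table; for the
    ``remission`` column, pre-treatment is always ignored because
    remission is undefined there by construction.  Raises if no
    participant survives the filter.
    """
    columns = [columns] if isinstance(columns, str) else list(columns)
    all_tps = [str(t) for t in table["timepoint"].drop_duplicates()]
    tps = [str(t) for t in (timepoints if timepoints is not None else all_tps)]

    keep = None
    for col in columns:
        col_tps = [t for t in tps if not (col == "remission" and t == "pre")]
        sub = table[table["timepoint"].astype(str).isin(col_tps)]
        complete = sub.groupby("participant_id")[col].apply(
            lambda s: s.notna().all()
        )
        keep = complete if keep is None else (keep & complete)
    kept_ids = keep[keep].index
    out = table[table["participant_id"].isin(kept_ids)].reset_index(drop=True)
    if out.empty:
        raise ValueError("complete-case filter removed every participant")
    return out


def run_excluding_unemployment(model, **fit_kwargs):
    """Re-run a fitted pipeline under the societal perspective with
    unemployment costs removed, returning the new results.

    The caller compares ``quadrants`` side by side with the base run;
    clinic/health-care outputs are identical to the base run because the
    exclusion only touches the societal total.
    """
    variant = model.with_perspectives(
        ["societal", "societal_excl_unemployment"]
    )
    return variant.fit(**fit_kwargs)
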