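"""Incremental cost-effectiveness: ICERs, bootstrap of the joint
(Δcost, Δeffect) distribution, cost-effectiveness-plane quadrants and
net-benefit acceptability curves.

The bootstrap resamples participants (all their timepoints together)
with replacement, stratified by arm with arm sizes preserved — the
standard choice for trial-based economic evaluation — and re-estimates
the group-difference contrasts in each replicate.  Incremental costs
and QALYs are difference-in-differences contrasts (change from
pre-treatment, intervention minus control); the incremental remission
effect is the arm difference in remission proportions at the timepoint
(remission has no pre-treatment value).  The default re-estimates the
mixed models per replicate; ``method="cellmeans"`` substitutes the
cell-mean difference-in-differences, a fast approximation that is exact
on balanced complete data.

The acceptability curve reports, per willingness-to-pay λ, the fraction
of replicates whose net monetary benefit λ·ΔE − ΔC is strictly positive
(a tie at exactly zero counts as not cost-effective; a measure-zero
event).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import inference
from .costing import Perspective

__all__ = [
    "CeacCurve",
    "icer",
    "net_benefit",
    "bootstrap_cea",
    "quadrant_proportions",
    "ceac",
    "point_estimates",
    "default_lambda_grid",
]

ANALYSIS_TIMEPOINTS = ("post", "followup")
#: clinic costs arise in the post-treatment period only; the clinic-
#: perspective contrast at follow-up is the (one-off) treatment-cost
#: difference, i.e. the post-period contrast carried forward
_CARRY_FORWARD = {"clinic": "post"}


def default_lambda_grid(max_lambda: float = 60000.0, step: float = 1000.0) -> np.ndarray:
    """Willingness-to-pay grid, $0 to $60,000 in $1,000 steps by default."""
    return np.arange(0.0, max_lambda + step / 2, step)


def icer(delta_cost: float, delta_effect: float) -> float:
    """Incremental cost-effectiveness ratio ΔC / ΔE.

    Undefined at ΔE = 0: raises ``ZeroDivisionError`` so the caller must
    report it as undefined rather than silently propagate an infinity.
    """
    if delta_effect == 0:
        raise ZeroDivisionError("ICER undefined: delta_effect is zero")
    return delta_cost / delta_effect


def net_benefit(lam: float, delta_effect, delta_cost):
    """Net monetary benefit λ·ΔE − ΔC (positive = cost-effective at λ)."""
    if lam < 0:
        raise ValueError("willingness-to-pay must be nonnegative")
    return lam * np.asarray(delta_effect) - np.asarray(delta_cost)


@dataclass
class CeacCurve:
    """Probability of cost-effectiveness over a willingness-to-pay grid."""

    lambda_grid: np.ndarray
    probability: np.ndarray
    outcome: str = ""
    perspective: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, float)
        self.probability = np.asarray(self.probability, float)
        if len(self.lambda_grid) != len(self.probability):
            raise ValueError("grid and probabilities differ in length")
        if len(self.lambda_grid) == 0:
            raise ValueError("empty willingness-to-pay grid")
        if not np.all(np.diff(self.lambda_grid) > 0):
            raise ValueError("lambda grid must be strictly ascending")
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValueError("probabilities outside [0,1]")

    def at(self, lam: float) -> float:
        """Probability at a grid value of λ."""
        i = np.nonzero(np.isclose(self.lambda_grid, lam))[0]
        if len(i) == 0:
            raise KeyError(f"λ={lam} not on the grid")
        return float(self.probability[i[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lambda": self.lambda_grid, "probability": self.probability}
        )


# ---------------------------------------------------------------------------
# resampling machinery
# ---------------------------------------------------------------------------


class _WideTrial:
    """Participant-major array view of the long table for fast resampling."""

    def __init__(self, table: pd.DataFrame, value_cols, timepoints):
        self.timepoints = list(timepoints)
        pids = table["participant_id"].unique()
        arm_of = table.drop_duplicates("participant_id").set_index("participant_id")[
            "arm"
        ]
        self.arms = arm_of.loc[pids].to_numpy()
        wide = table.pivot(
            index="participant_id", columns="timepoint", values=list(value_cols)
        ).loc[pids]
        self.arrays = {
            col: np.column_stack(
                [wide[(col, tp)].to_numpy(float) for tp in self.timepoints]
            )
            for col in value_cols
        }
        self.arm_index = {
            arm: np.nonzero(self.arms == arm)[0] for arm in ("control", "intervention")
        }

    def resample(self, rng: np.random.Generator) -> np.ndarray:
        """Indices of a stratified resample preserving arm sizes."""
        parts = [
            rng.choice(idx, size=len(idx), replace=True)
            for arm, idx in self.arm_index.items()
        ]
        return np.concatenate(parts)

    def cell_means(self, col: str, idx: np.ndarray) -> dict:
        out = {}
        for arm, rows in (
            ("control", idx[: len(self.arm_index["control"])]),
            ("intervention", idx[len(self.arm_index["control"]) :]),
        ):
            vals = self.arrays[col][rows]
            with warnings.catch_warnings():
                # all-NaN cells (e.g. remission at pre) are legitimately NaN
                warnings.simplefilter("ignore", RuntimeWarning)
                out[arm] = np.nanmean(vals, axis=0)
        return out

    def long_frame(self, cols, idx: np.ndarray) -> pd.DataFrame:
        """Rebuild a long table from resampled rows; duplicated draws of a
        participant become distinct grouping units."""
        n, T = len(idx), len(self.timepoints)
        data = {
            "participant_id": np.repeat(np.arange(n), T),
            "arm": np.repeat(self.arms[idx], T),
            "timepoint": np.tile(np.asarray(self.timepoints, object), n),
        }
        for col in cols:
            data[col] = self.arrays[col][idx].ravel()
        return pd.DataFrame(data)


def _did_from_cells(cells: dict, timepoints, has_pre: bool) -> dict:
    """DiD per analysis timepoint from arm x timepoint mean vectors."""
    tp_pos = {tp: i for i, tp in enumerate(timepoints)}
    out = {}
    for tp in ANALYSIS_TIMEPOINTS:
        if tp not in tp_pos:
            continue
        di = cells["intervention"][tp_pos[tp]]
        dc = cells["control"][tp_pos[tp]]
        if has_pre and "pre" in tp_pos:
            di -= cells["intervention"][tp_pos["pre"]]
            dc -= cells["control"][tp_pos["pre"]]
        out[tp] = di - dc
    return out


def _degenerate_cols(table: pd.DataFrame, cols) -> frozenset:
    """Cost columns constant within every arm x timepoint cell (e.g. the
    clinic perspective): no sampling variation, so per-replicate mixed
    models are singular and cell means are exact."""
    out = set()
    for col in cols:
        sd = table.groupby(["arm", "timepoint"], observed=True)[col].std(ddof=0)
        if np.all(sd.fillna(0.0) < 1e-12):
            out.add(col)
    return frozenset(out)


def _estimate_deltas(
    wide: _WideTrial,
    idx: np.ndarray,
    cost_cols,
    *,
    method: str,
    cellmean_only: frozenset = frozenset(),
) -> dict:
    """One replicate's contrasts: {('cost', perspective, tp) | ('qaly', tp)
    | ('remission', tp): value}."""
    est: dict = {}
    if method == "cellmeans":
        cells = wide.cell_means("eq5d_index", idx)
        for tp, v in _did_from_cells(cells, wide.timepoints, has_pre=True).items():
            est[("qaly", tp)] = v
        for col in cost_cols:
            cells = wide.cell_means(col, idx)
            for tp, v in _did_from_cells(cells, wide.timepoints, has_pre=True).items():
                est[("cost", col, tp)] = v
    elif method == "mixed":
        frame = wide.long_frame(["eq5d_index"] + list(cost_cols), idx)
        fit = inference.fit_mixed_model(frame, "eq5d_index")
        for tp in ANALYSIS_TIMEPOINTS:
            if tp in wide.timepoints:
                est[("qaly", tp)] = inference.did_contrast(fit, tp).estimate
        for col in cost_cols:
            if col in cellmean_only:
                cells = wide.cell_means(col, idx)
                for tp, v in _did_from_cells(
                    cells, wide.timepoints, has_pre=True
                ).items():
                    est[("cost", col, tp)] = v
                continue
            fitc = inference.fit_mixed_model(frame, col)
            for tp in ANALYSIS_TIMEPOINTS:
                if tp in wide.timepoints:
                    est[("cost", col, tp)] = inference.did_contrast(fitc, tp).estimate
    else:
        raise ValueError("method must be 'mixed' or 'cellmeans'")

    # remission: model-free arm proportions (no pre-treatment value exists)
    cells = wide.cell_means("remission", idx)
    for tp, v in _did_from_cells(cells, wide.timepoints, has_pre=False).items():
        est[("remission", tp)] = v

    for persp, src_tp in _CARRY_FORWARD.items():
        if persp in cost_cols and ("cost", persp, src_tp) in est:
            for tp in ANALYSIS_TIMEPOINTS:
                if tp != src_tp and ("cost", persp, tp) in est:
                    est[("cost", persp, tp)] = est[("cost", persp, src_tp)]
    return est


def bootstrap_cea(
    table: pd.DataFrame,
    *,
    perspectives=("societal",),
    B: int = 1000,
    seed: int | None = None,
    method: str = "mixed",
    max_redraws: int = 50,
) -> pd.DataFrame:
    """Bootstrap the joint distribution of incremental costs and effects.

    *table* is a participant x timepoint frame carrying ``eq5d_index``,
    ``remission`` and one cost column per requested perspective.
    Returns a tidy frame with one row per replicate x outcome x
    perspective x timepoint: columns ``replicate, outcome, perspective,
    timepoint, delta_effect, delta_cost``.  Reproducible from *seed*;
    a non-converging mixed-model replicate is redrawn and the count is
    recorded in ``result.attrs["n_redrawn"]``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    persp = [Perspective(p).value for p in perspectives]
    rng = np.random.default_rng(seed)
    timepoints = [str(t) for t in table["timepoint"].drop_duplicates()]
    value_cols = ["eq5d_index", "remission"] + persp
    wide = _WideTrial(table, value_cols, timepoints)
    cellmean_only = _degenerate_cols(table, persp)

    rows = []
    n_redrawn = 0
    for b in range(B):
        for _attempt in range(max_redraws):
            idx = wide.resample(rng)
            try:
                est = _estimate_deltas(
                    wide, idx, persp, method=method, cellmean_only=cellmean_only
                )
                break
            except inference.ConvergenceError:
                n_redrawn += 1
        else:
            raise inference.ConvergenceError(
                f"replicate {b}: no convergence in {max_redraws} redraws"
            )
        for p in persp:
            for tp in ANALYSIS_TIMEPOINTS:
                if ("cost", p, tp) not in est:
                    continue
                for outcome in ("remission", "qaly"):
                    rows.append(
                        {
                            "replicate": b,
                            "outcome": outcome,
                            "perspective": p,
                            "timepoint": tp,
                            "delta_effect": est[(outcome, tp)],
                            "delta_cost": est[("cost", p, tp)],
                        }
                    )
    out = pd.DataFrame(rows)
    out.attrs["n_redrawn"] = n_redrawn
    out.attrs["method"] = method
    out.attrs["B"] = B
    return out


def point_estimates(
    table: pd.DataFrame,
    *,
    perspectives=("societal",),
    method: str = "mixed",
) -> pd.DataFrame:
    """Full-sample contrasts in the same tidy layout as the bootstrap
    (replicate = -1), with the ICER appended where defined."""
    persp = [Perspective(p).value for p in perspectives]
    timepoints = [str(t) for t in table["timepoint"].drop_duplicates()]
    wide = _WideTrial(table, ["eq5d_index", "remission"] + persp, timepoints)
    idx = np.concatenate([wide.arm_index["control"], wide.arm_index["intervention"]])
    est = _estimate_deltas(
        wide, idx, persp, method=method, cellmean_only=_degenerate_cols(table, persp)
    )
    rows = []
    for p in persp:
        for tp in ANALYSIS_TIMEPOINTS:
            if ("cost", p, tp) not in est:
                continue
            for outcome in ("remission", "qaly"):
                de, dc = est[(outcome, tp)], est[("cost", p, tp)]
                try:
                    ratio = icer(dc, de)
                except ZeroDivisionError:
                    ratio = np.nan
                rows.append(
                    {
                        "outcome": outcome,
                        "perspective": p,
                        "timepoint": tp,
                        "delta_effect": de,
                        "delta_cost": dc,
                        "icer": ratio,
                    }
                )
    return pd.DataFrame(rows)


def quadrant_proportions(replicates: pd.DataFrame) -> pd.Series:
    """Cost-effectiveness-plane quadrant shares of a replicate set.

    NE = more effective & more costly, NW = less effective & more
    costly, SE = more effective & cost-saving, SW = less effective &
    cost-saving.  Zero differences count to the positive side; the four
    proportions sum to exactly 1.
    """
    if len(replicates) == 0:
        raise ValueError("empty replicate set")
    de = replicates["delta_effect"].to_numpy(float)
    dc = replicates["delta_cost"].to_numpy(float)
    n = len(de)
    ne = ((de >= 0) & (dc >= 0)).sum() / n
    nw = ((de < 0) & (dc >= 0)).sum() / n
    se = ((de >= 0) & (dc < 0)).sum() / n
    sw = ((de < 0) & (dc < 0)).sum() / n
    return pd.Series({"NE": ne, "NW": nw, "SE": se, "SW": sw})


def ceac(
    replicates: pd.DataFrame,
    lambda_grid=None,
    **labels,
) -> CeacCurve:
    """Acceptability curve: fraction of replicates with positive net
    monetary benefit at each willingness-to-pay value."""
    if len(replicates) == 0:
        raise ValueError("empty replicate set")
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    if len(grid) == 0:
        raise ValueError("empty willingness-to-pay grid")
    de = replicates["delta_effect"].to_numpy(float)
    dc = replicates["delta_cost"].to_numpy(float)
    nb = grid[:, None] * de[None, :] - dc[None, :]
    prob = (nb > 0).mean(axis=1)
    return CeacCurve(grid, prob, **labels)
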