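"""Statsmodels-style front end: a :class:`CostEffectivenessModel` built
from participant-level trial data whose :meth:`~CostEffectivenessModel.fit`
returns a :class:`CEAResults` carrying contrasts, ICERs, bootstrap
replicates, quadrant proportions and acceptability curves.

Typical use::

    from trialcea import CostEffectivenessModel, TrialConfig

    model = CostEffectivenessModel.simulate(TrialConfig(), seed=1)
    res = model.fit(bootstrap_reps=1000, seed=1)
    print(res.summary())
    res.save("out/")
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import cea, inference, outcomes, sensitivity, simulate
from .costing import Perspective, TariffTable, cost_table

__all__ = ["CostEffectivenessModel", "CEAResults"]

DEFAULT_PERSPECTIVES = ("clinic", "health_care", "societal")


class CostEffectivenessModel:
    """Trial-based cost-effectiveness analysis of a two-arm trial.

    Parameters
    ----------
    data : DataFrame
        One row per participant x timepoint with ``participant_id``,
        ``arm`` (control/intervention), ``timepoint`` (pre/post/followup),
        ``remission`` (0/1, undefined at pre), ``eq5d_index`` (or raw
        EQ-5D domain-level columns) and TIC-P resource-use items.
    tariff : TariffTable, optional
        Unit costs and scalar rates; defaults to the 2014 Swedish-style
        tariff.
    value_set : ValueSet, optional
        Used to derive ``eq5d_index`` when the data carry raw domain
        levels instead of a precomputed index.
    perspectives : sequence of Perspective
        Costing perspectives analysed (default clinic, health care,
        societal).
    lambda_grid : array, optional
        Willingness-to-pay grid for acceptability curves.
    complete_case : bool
        Restrict to participants with complete outcome and cost data
        (per-analysis filtering is available through
        :mod:`trialcea.sensitivity`; this flag applies a joint filter).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        tariff: TariffTable | None = None,
        value_set=None,
        perspectives=DEFAULT_PERSPECTIVES,
        lambda_grid=None,
        complete_case: bool = False,
    ):
        self.tariff = tariff or TariffTable()
        self.perspectives = tuple(Perspective(p).value for p in perspectives)
        self.lambda_grid = (
            cea.default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
        )
        self.complete_case = bool(complete_case)
        self.raw_data = data

        data = data.copy()
        if "eq5d_index" not in data.columns:
            vs = value_set or outcomes.ValueSet.toy()
            data["eq5d_index"] = [
                outcomes.eq5d_index([row[d] for d in outcomes.EQ5D_DOMAINS], vs)
                if not any(pd.isna(row[d]) for d in outcomes.EQ5D_DOMAINS)
                else np.nan
                for _, row in data.iterrows()
            ]
        self._validate(data)

        costs = cost_table(data, self.tariff)  # row-aligned with data
        keep = ["participant_id", "arm", "timepoint", "remission", "eq5d_index"]
        merged = data[keep].copy()
        cost_cols = [p.value for p in Perspective] + ["unemployment"]
        for col in cost_cols:
            merged[col] = costs[col].to_numpy()
        self.data = merged

        if self.complete_case:
            cols = ["eq5d_index", "remission"] + list(self.perspectives)
            self.data = sensitivity.complete_case_filter(self.data, cols)

    @staticmethod
    def _validate(data: pd.DataFrame) -> None:
        required = {"participant_id", "arm", "timepoint"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data lacks required column(s): {sorted(missing)}")
        arms = set(data["arm"].unique())
        if not arms <= {"control", "intervention"}:
            raise ValueError(f"inconsistent arm labels: {sorted(arms)}")
        dup = data.duplicated(["participant_id", "timepoint"])
        if dup.any():
            raise ValueError("a participant appears more than once per timepoint")

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_csv(cls, path, *, tariff_csv=None, value_set_csv=None, **kwargs):
        data = simulate.read_trial_csv(path)
        tariff = TariffTable.from_csv(tariff_csv) if tariff_csv else None
        vs = outcomes.ValueSet.from_csv(value_set_csv) if value_set_csv else None
        return cls(data, tariff=tariff, value_set=vs, **kwargs)

    @classmethod
    def simulate(
        cls,
        config: simulate.TrialConfig | None = None,
        *,
        seed: int | None = None,
        missingness: bool = True,
        **kwargs,
    ):
        """Build the model from a freshly generated synthetic trial."""
        config = config or simulate.TrialConfig()
        table = simulate.generate_trial(config, seed=seed)
        if missingness:
            table = simulate.apply_missingness(table, config, seed=seed)
        obj = cls(table, **kwargs)
        obj.config = config
        return obj

    def with_perspectives(self, perspectives) -> "CostEffectivenessModel":
        """Copy of the model analysing a different perspective set."""
        new = CostEffectivenessModel.__new__(CostEffectivenessModel)
        new.__dict__.update(self.__dict__)
        new.perspectives = tuple(Perspective(p).value for p in perspectives)
        return new

    # -- estimation ------------------------------------------------------
    def fit(
        self,
        *,
        bootstrap_reps: int = 1000,
        seed: int | None = None,
        bootstrap_method: str = "mixed",
        sigma: str = "residual",
    ) -> "CEAResults":
        """Fit the mixed models, bootstrap the contrasts and assemble
        ICERs, quadrant proportions and acceptability curves."""
        fits: dict[str, inference.MixedModelFit] = {}
        fits["eq5d_index"] = inference.fit_mixed_model(self.data, "eq5d_index")
        for p in self.perspectives:
            if self._degenerate(p):
                continue  # deterministic costs (clinic): cell means suffice
            fits[p] = inference.fit_mixed_model(self.data, p)

        remission_fit = inference.fit_remission_model(self.data)

        contrast_rows = []
        for name, fit in fits.items():
            for tp in ("post", "followup"):
                c = inference.did_contrast(fit, tp)
                lo, hi = c.conf_int()
                contrast_rows.append(
                    {
                        "outcome": name,
                        "timepoint": tp,
                        "estimate": c.estimate,
                        "se": c.se,
                        "pvalue": c.pvalue,
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
        contrasts = pd.DataFrame(contrast_rows)

        es_rows = []
        ufit = fits["eq5d_index"]
        for tp in ("post", "followup"):
            for arm in ("control", "intervention"):
                ch = inference.within_arm_change(ufit, arm, tp)
                es_rows.append(
                    {
                        "kind": "within",
                        "arm": arm,
                        "timepoint": tp,
                        "d": inference.cohens_d(ufit, ch, sigma=sigma),
                    }
                )
            did = inference.did_contrast(ufit, tp)
            es_rows.append(
                {
                    "kind": "between",
                    "arm": "intervention-control",
                    "timepoint": tp,
                    "d": inference.cohens_d(ufit, did, sigma=sigma),
                }
            )
        effect_sizes = pd.DataFrame(es_rows)

        # headline contrasts always come from the mixed models; the
        # bootstrap method only governs the replicates
        estimates = cea.point_estimates(
            self.data, perspectives=self.perspectives, method="mixed"
        )
        replicates = cea.bootstrap_cea(
            self.data,
            perspectives=self.perspectives,
            B=bootstrap_reps,
            seed=seed,
            method=bootstrap_method,
        )

        quadrant_rows = []
        curves = {}
        for (outcome, p, tp), grp in replicates.groupby(
            ["outcome", "perspective", "timepoint"], observed=True
        ):
            q = cea.quadrant_proportions(grp)
            quadrant_rows.append(
                {"outcome": outcome, "perspective": p, "timepoint": tp, **q.to_dict()}
            )
            curves[(outcome, p, tp)] = cea.ceac(
                grp, self.lambda_grid, outcome=outcome, perspective=p, timepoint=tp
            )
        quadrants = pd.DataFrame(quadrant_rows)

        return CEAResults(
            model=self,
            fits=fits,
            remission_fit=remission_fit,
            contrasts=contrasts,
            effect_sizes=effect_sizes,
            estimates=estimates,
            replicates=replicates,
            quadrants=quadrants,
            ceac_curves=curves,
            seed=seed,
            bootstrap_reps=bootstrap_reps,
            bootstrap_method=bootstrap_method,
        )

    def _degenerate(self, col: str) -> bool:
        """True when a cost column is constant within every arm x timepoint
        cell (no sampling variation; e.g. the clinic perspective)."""
        sd = self.data.groupby(["arm", "timepoint"], observed=True)[col].std(ddof=0)
        return bool(np.all(sd.fillna(0.0) < 1e-12))

    # -- descriptives ----------------------------------------------------
    def descriptives(self) -> pd.DataFrame:
        """Arm x timepoint means of remission, EQ-5D and perspective costs
        with Wald 95% confidence intervals."""
        rows = []
        cols = ["remission", "eq5d_index"] + list(self.perspectives)
        for (arm, tp), grp in self.data.groupby(["arm", "timepoint"], observed=True):
            for col in cols:
                vals = grp[col].dropna().to_numpy(float)
                if len(vals) == 0:
                    continue
                m = vals.mean()
                se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
                h = stats.norm.ppf(0.975) * se
                rows.append(
                    {
                        "arm": arm,
                        "timepoint": tp,
                        "measure": col,
                        "n": len(vals),
                        "mean": m,
                        "ci_low": m - h,
                        "ci_high": m + h,
                    }
                )
        return pd.DataFrame(rows)


class CEAResults:
    """Results of a fitted :class:`CostEffectivenessModel`.

    Attributes
    ----------
    contrasts : DataFrame
        Mixed-model difference-in-differences contrasts (EQ-5D and each
        stochastic cost perspective) with SEs, p-values and Wald CIs.
    effect_sizes : DataFrame
        Cohen's d for within-arm changes and between-group contrasts of
        the EQ-5D index.
    estimates : DataFrame
        Full-sample Δcost, Δeffect and ICER per outcome x perspective x
        timepoint.
    replicates : DataFrame
        Bootstrap draws of (Δcost, Δeffect).
    quadrants : DataFrame
        Cost-effectiveness-plane quadrant proportions per analysis.
    ceac_curves : dict
        ``(outcome, perspective, timepoint) -> CeacCurve``.
    """

    def __init__(
        self,
        *,
        model,
        fits,
        remission_fit,
        contrasts,
        effect_sizes,
        estimates,
        replicates,
        quadrants,
        ceac_curves,
        seed,
        bootstrap_reps,
        bootstrap_method,
    ):
        self.model = model
        self.fits = fits
        self.remission_fit = remission_fit
        self.contrasts = contrasts
        self.effect_sizes = effect_sizes
        self.estimates = estimates
        self.replicates = replicates
        self.quadrants = quadrants
        self.ceac_curves = ceac_curves
        self.seed = seed
        self.bootstrap_reps = bootstrap_reps
        self.bootstrap_method = bootstrap_method

    def icer(self, outcome: str, perspective: str, timepoint: str) -> float:
        row = self.estimates[
            (self.estimates["outcome"] == outcome)
            & (self.estimates["perspective"] == perspective)
            & (self.estimates["timepoint"] == timepoint)
        ]
        if row.empty:
            raise KeyError((outcome, perspective, timepoint))
        return float(row["icer"].iloc[0])

    def ceac_at(self, lam: float, outcome: str, perspective: str, timepoint: str) -> float:
        return self.ceac_curves[(outcome, perspective, timepoint)].at(lam)

    def summary(self) -> str:
        """Plain-text report in the spirit of a statsmodels summary."""
        lines = []
        w = 78
        lines.append("=" * w)
        lines.append("Trial-based cost-effectiveness analysis".center(w))
        lines.append("=" * w)
        n_part = self.model.data["participant_id"].nunique()
        lines.append(
            f"Participants: {n_part}   Bootstrap: B={self.bootstrap_reps} "
            f"({self.bootstrap_method}, seed={self.seed})   "
            f"Perspectives: {', '.join(self.model.perspectives)}"
        )
        lines.append("-" * w)
        lines.append("Remission odds ratios (random-intercept logistic)")
        lines.append(
            self.remission_fit.odds_ratios.round(3).to_string()
        )
        lines.append("-" * w)
        lines.append("Difference-in-differences contrasts (mixed models, ML)")
        lines.append(self.contrasts.round(4).to_string(index=False))
        lines.append("-" * w)
        lines.append("Effect sizes (Cohen's d, EQ-5D)")
        lines.append(self.effect_sizes.round(3).to_string(index=False))
        lines.append("-" * w)
        lines.append("Incremental cost-effectiveness (USD per unit effect)")
        est = self.estimates.copy()
        est[["delta_cost", "icer"]] = est[["delta_cost", "icer"]].round(0)
        est["delta_effect"] = est["delta_effect"].round(3)
        lines.append(est.to_string(index=False))
        lines.append("-" * w)
        lines.append("Cost-effectiveness plane quadrant proportions (bootstrap)")
        lines.append(self.quadrants.round(3).to_string(index=False))
        lines.append("=" * w)
        return "\n".join(lines)

    def save(self, outdir, *, variant: str = "base") -> dict:
        """Write the result bundle as CSV/JSON files; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _write(df: pd.DataFrame, name: str):
            df = df.copy()
            df.insert(0, "variant", variant)
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p

        _write(self.model.descriptives(), "descriptives")
        _write(self.contrasts, "contrasts")
        _write(self.effect_sizes, "effect_sizes")
        _write(self.estimates, "icer_table")
        _write(self.replicates, "replicates")
        ceac_frames = []
        for (outcome, p, tp), curve in self.ceac_curves.items():
            f = curve.to_frame()
            f["outcome"], f["perspective"], f["timepoint"] = outcome, p, tp
            ceac_frames.append(f)
        _write(pd.concat(ceac_frames, ignore_index=True), "ceac")

        spath = outdir / "summary.json"
        spath.write_text(
            json.dumps(
                {
                    "variant": variant,
                    "contrasts": self.contrasts.to_dict(orient="records"),
                    "icer_table": self.estimates.to_dict(orient="records"),
                    "remission_odds_ratios": self.remission_fit.odds_ratios.reset_index().to_dict(
                        orient="records"
                    ),
                },
                indent=2,
                default=float,
            )
        )
        paths["summary"] = spath

        qpath = outdir / "quadrants.json"
        payload = {
            "variant": variant,
            "quadrants": self.quadrants.to_dict(orient="records"),
        }
        qpath.write_text(json.dumps(payload, indent=2))
        paths["quadrants"] = qpath

        log = outdir / "run_log.txt"
        import statsmodels

        log.write_text(
            "\n".join(
                [
                    f"variant: {variant}",
                    f"seed: {self.seed}",
                    f"bootstrap_reps: {self.bootstrap_reps}",
                    f"bootstrap_method: {self.bootstrap_method}",
                    f"replicates_redrawn: {self.replicates.attrs.get('n_redrawn', 0)}",
                    f"numpy: {np.__version__}",
                    f"pandas: {pd.__version__}",
                    f"statsmodels: {statsmodels.__version__}",
                ]
            )
            + "\n"
        )
        paths["run_log"] = log
        return paths
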