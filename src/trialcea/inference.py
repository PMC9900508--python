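"""Repeated-measures inference: linear mixed models, difference-in-
differences contrasts, effect sizes and remission odds ratios.

Outcomes (EQ-5D index) and costs are analysed on their raw scale with a
linear mixed model carrying fixed effects of group, time (categorical,
pre-treatment reference), their interaction, and a participant-level
random intercept, fitted by maximum likelihood so that missing-at-random
outcome values are handled by the likelihood with no imputation.  The
group x time interaction coefficient at a timepoint *is* the
difference-in-differences: (intervention change from pre) minus
(control change from pre), with the sign convention that a costlier /
more improved intervention arm gives a positive contrast.

Remission (a binary status defined only from post-treatment onwards) is
modelled with a random-intercept logistic regression; a model-free
marginal 2x2 odds ratio is provided as a cross-check, since conditional
(subject-specific) and marginal odds ratios differ in scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "MixedModelFit",
    "Contrast",
    "ConvergenceError",
    "fit_mixed_model",
    "did_contrast",
    "within_arm_change",
    "interaction_wald",
    "cohens_d",
    "fit_remission_model",
    "marginal_odds_ratio",
    "RemissionFit",
]

ARMS = ("control", "intervention")
TIMEPOINTS = ("pre", "post", "followup")


class ConvergenceError(RuntimeError):
    """Mixed-model optimisation failed to converge."""


@dataclass
class Contrast:
    """One estimated group difference (DiD or within-arm change)."""

    estimate: float
    se: float
    timepoint: str
    outcome: str

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be nonnegative")

    @property
    def z(self) -> float:
        return self.estimate / self.se if self.se > 0 else np.nan

    @property
    def pvalue(self) -> float:
        return 2 * stats.norm.sf(abs(self.z))

    def conf_int(self, alpha: float = 0.05):
        h = stats.norm.ppf(1 - alpha / 2) * self.se
        return self.estimate - h, self.estimate + h


@dataclass
class MixedModelFit:
    """ML-fitted random-intercept model for one outcome.

    Wraps the statsmodels result with the quantities the cost-
    effectiveness pipeline consumes: fixed effects, the arm x timepoint
    least-squares means, and the two variance components.
    """

    outcome: str
    fe_params: pd.Series
    cov_params: pd.DataFrame
    random_intercept_var: float
    residual_var: float
    lsmeans: pd.DataFrame  # arm x timepoint
    converged: bool
    method: str = "ML"
    n_obs: int = 0
    timepoints: tuple = TIMEPOINTS
    result: object = field(default=None, repr=False)

    @property
    def residual_sd(self) -> float:
        return float(np.sqrt(self.residual_var))

    @property
    def total_sd(self) -> float:
        return float(np.sqrt(self.residual_var + self.random_intercept_var))

    def interaction_term(self, timepoint: str) -> str:
        return (
            "C(arm, Treatment('control'))[T.intervention]:"
            f"C(timepoint, Treatment('pre'))[T.{timepoint}]"
        )


def _formula(outcome: str) -> str:
    return (
        f"{outcome} ~ C(arm, Treatment('control')) * C(timepoint, Treatment('pre'))"
    )


def fit_mixed_model(
    table: pd.DataFrame,
    outcome: str,
    *,
    groups: str = "participant_id",
    maxiter: int = 200,
    tol: float = 1e-8,
) -> MixedModelFit:
    """Fit the random-intercept model ``outcome ~ arm * time`` by ML.

    Rows with a missing outcome are dropped from the likelihood (the
    MAR-valid mixed-model treatment of missing data); at least two arms
    and two timepoints with data are required.  Non-convergence raises
    :class:`ConvergenceError` rather than returning silently.
    """
    data = table.dropna(subset=[outcome]).copy()
    if data["arm"].nunique() < 2 or data["timepoint"].nunique() < 2:
        raise ValueError("need data in >= 2 arms and >= 2 timepoints")
    cells = data.groupby(["arm", "timepoint"], observed=True)[outcome].size()
    if (cells == 0).any():
        raise ValueError("an arm x timepoint cell has no observations")

    # fit on a standardised outcome for numerical stability (costs are in
    # the thousands of dollars); estimates are rescaled back afterwards
    y_scale = float(data[outcome].std(ddof=1))
    if not np.isfinite(y_scale) or y_scale == 0:
        raise ValueError(f"outcome {outcome!r} has zero variance")
    work = data.copy()
    work["_y"] = work[outcome] / y_scale

    model = smf.mixedlm(_formula("_y"), work, groups=work[groups])
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for optimiser in ("lbfgs", "bfgs", "powell"):
            try:
                res = model.fit(reml=False, maxiter=maxiter, method=optimiser)
            except np.linalg.LinAlgError:
                continue
            if res.converged:
                break
    if res is None or not res.converged:
        raise ConvergenceError(f"mixed model for {outcome!r} did not converge")

    timepoints = tuple(t for t in TIMEPOINTS if t in set(data["timepoint"]))
    fe = res.fe_params * y_scale
    cov_fe = (
        res.cov_params().loc[res.fe_params.index, res.fe_params.index] * y_scale**2
    )
    return MixedModelFit(
        outcome=outcome,
        fe_params=fe,
        cov_params=cov_fe,
        random_intercept_var=float(np.asarray(res.cov_re)[0, 0]) * y_scale**2,
        residual_var=float(res.scale) * y_scale**2,
        lsmeans=_lsmeans(fe, timepoints),
        converged=bool(res.converged),
        n_obs=int(res.nobs),
        timepoints=timepoints,
        result=res,
    )


def _lsmeans(fe: pd.Series, timepoints) -> pd.DataFrame:
    """Arm x timepoint cell means implied by the fixed effects."""
    arm_term = "C(arm, Treatment('control'))[T.intervention]"
    out = pd.DataFrame(index=list(ARMS), columns=list(timepoints), dtype=float)
    for arm in ARMS:
        for tp in timepoints:
            mu = fe["Intercept"]
            if arm == "intervention":
                mu += fe[arm_term]
            if tp != "pre":
                time_term = f"C(timepoint, Treatment('pre'))[T.{tp}]"
                mu += fe[time_term]
                if arm == "intervention":
                    mu += fe[f"{arm_term}:{time_term}"]
            out.loc[arm, tp] = mu
    out.index.name = "arm"
    out.columns.name = "timepoint"
    return out


def did_contrast(fit: MixedModelFit, timepoint: str) -> Contrast:
    """Difference-in-differences at *timepoint*: the group x time
    interaction coefficient (intervention change minus control change).
    Undefined at the pre-treatment reference."""
    if timepoint == "pre":
        raise ValueError("no change from pre-treatment is defined at pre-treatment")
    term = fit.interaction_term(timepoint)
    if term not in fit.fe_params.index:
        raise KeyError(f"timepoint {timepoint!r} not in the fitted model")
    return Contrast(
        estimate=float(fit.fe_params[term]),
        se=float(np.sqrt(fit.cov_params.loc[term, term])),
        timepoint=timepoint,
        outcome=fit.outcome,
    )


def within_arm_change(fit: MixedModelFit, arm: str, timepoint: str) -> Contrast:
    """Change from pre-treatment within one arm, with delta-method SE."""
    if timepoint == "pre":
        raise ValueError("no change from pre-treatment is defined at pre-treatment")
    time_term = f"C(timepoint, Treatment('pre'))[T.{timepoint}]"
    terms = [time_term]
    if arm == "intervention":
        terms.append(fit.interaction_term(timepoint))
    est = float(sum(fit.fe_params[t] for t in terms))
    var = float(sum(fit.cov_params.loc[a, b] for a in terms for b in terms))
    return Contrast(est, float(np.sqrt(var)), timepoint, f"{fit.outcome}[{arm}]")


def interaction_wald(fit: MixedModelFit) -> tuple[float, int, float]:
    """Joint Wald chi-square test that all group x time coefficients are 0."""
    terms = [fit.interaction_term(tp) for tp in fit.timepoints if tp != "pre"]
    b = fit.fe_params[terms].to_numpy()
    V = fit.cov_params.loc[terms, terms].to_numpy()
    chi2 = float(b @ np.linalg.solve(V, b))
    df = len(terms)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def cohens_d(
    fit: MixedModelFit, contrast: Contrast, *, sigma: str = "residual"
) -> float:
    """Standardise a model contrast: estimate / sigma.

    ``sigma="residual"`` (default) uses the mixed model's residual SD;
    ``sigma="total"`` uses sqrt(random-intercept variance + residual
    variance).  Zero sigma is an error.
    """
    if sigma == "residual":
        s = fit.residual_sd
    elif sigma == "total":
        s = fit.total_sd
    else:
        raise ValueError("sigma must be 'residual' or 'total'")
    if s == 0:
        raise ZeroDivisionError("sigma is zero; effect size undefined")
    return contrast.estimate / s


# ---------------------------------------------------------------------------
# remission (binary) models
# ---------------------------------------------------------------------------


@dataclass
class RemissionFit:
    """Random-intercept logistic fit for remission at post/follow-up.

    ``odds_ratios`` holds per-timepoint conditional (subject-specific)
    ORs with delta-method SEs and Wald p-values; ``marginal`` holds the
    model-free 2x2 odds ratios, which are on a different (population-
    averaged) scale.  ``penalized`` flags that the regularised
    variational fit was relied on under (near-)separation.
    """

    odds_ratios: pd.DataFrame
    marginal: pd.DataFrame
    proportions: pd.DataFrame  # arm x timepoint remission proportions
    penalized: bool = False


def marginal_odds_ratio(table: pd.DataFrame, timepoint: str) -> tuple[float, float]:
    """2x2 odds ratio (intervention vs control) at one timepoint with a
    Haldane-Anscombe 0.5 correction when a cell is empty; returns
    (OR, SE of log OR)."""
    sub = table[(table["timepoint"] == timepoint)].dropna(subset=["remission"])
    counts = []
    for arm in ("intervention", "control"):
        r = sub[sub["arm"] == arm]["remission"]
        counts.extend([float((r == 1).sum()), float((r == 0).sum())])
    a, b, c, d = counts  # int remit / int not / ctrl remit / ctrl not
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a / b) / (c / d)
    se_log = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(or_), float(se_log)


def fit_remission_model(table: pd.DataFrame) -> RemissionFit:
    """Fit the random-intercept logistic remission model.

    Uses post-treatment and follow-up rows (remission is undefined at
    pre-treatment).  The variational-Bayes fit of the mixed logistic
    model provides weak regularisation, which also serves as the
    penalised fallback under complete separation; per-timepoint
    conditional ORs come from the arm main effect (post) and its sum
    with the interaction (follow-up).

    The random-effects design holds one column per participant, so this
    is intended for trial-sized samples (hundreds of participants, not
    tens of thousands); the marginal 2x2 estimator has no such limit.
    """
    data = table.dropna(subset=["remission"]).copy()
    data = data[data["timepoint"] != "pre"]
    if data.empty:
        raise ValueError("no remission observations at post/follow-up")
    data["remission"] = data["remission"].astype(int)

    tps = [t for t in ("post", "followup") if t in set(data["timepoint"])]
    ref = tps[0]
    formula = (
        "remission ~ C(arm, Treatment('control')) "
        f"* C(timepoint, Treatment('{ref}'))"
        if len(tps) > 1
        else "remission ~ C(arm, Treatment('control'))"
    )

    separation = any(
        data[(data["arm"] == a) & (data["timepoint"] == t)]["remission"].nunique() < 2
        for a in ARMS
        for t in tps
    )
    model = BinomialBayesMixedGLM.from_formula(
        formula, {"participant": "0 + C(participant_id)"}, data
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit_vb()

    names = list(res.model.exog_names)
    arm_term = "C(arm, Treatment('control'))[T.intervention]"
    mean = pd.Series(res.fe_mean, index=names)
    sd = pd.Series(res.fe_sd, index=names)

    rows = []
    for tp in tps:
        if tp == ref:
            log_or, se = mean[arm_term], sd[arm_term]
        else:
            inter = (
                f"{arm_term}:C(timepoint, Treatment('{ref}'))[T.{tp}]"
            )
            log_or = mean[arm_term] + mean[inter]
            # mean-field posterior: cross-covariance taken as zero
            se = float(np.sqrt(sd[arm_term] ** 2 + sd[inter] ** 2))
        z = log_or / se
        rows.append(
            {
                "timepoint": tp,
                "odds_ratio": float(np.exp(log_or)),
                "se": float(np.exp(log_or) * se),
                "se_log_or": float(se),
                "pvalue": float(2 * stats.norm.sf(abs(z))),
            }
        )
    conditional = pd.DataFrame(rows).set_index("timepoint")

    marg_rows = []
    for tp in tps:
        or_, se_log = marginal_odds_ratio(table, tp)
        z = np.log(or_) / se_log
        marg_rows.append(
            {
                "timepoint": tp,
                "odds_ratio": or_,
                "se_log_or": se_log,
                "pvalue": float(2 * stats.norm.sf(abs(z))),
            }
        )
    marginal = pd.DataFrame(marg_rows).set_index("timepoint")

    props = (
        data.groupby(["arm", "timepoint"], observed=True)["remission"]
        .mean()
        .unstack("timepoint")
        .reindex(index=list(ARMS), columns=tps)
    )
    return RemissionFit(
        odds_ratios=conditional,
        marginal=marginal,
        proportions=props,
        penalized=separation,
    )
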