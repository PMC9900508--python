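"""Synthetic two-arm trial generator.

Emulates a 47-per-arm randomised trial with three assessment points
(pre-treatment, post-treatment at 3 months, follow-up at 6 months) and
the statistical structure the downstream analysis assumes:

* remission drawn Bernoulli per arm x timepoint (undefined at pre);
* EQ-5D utility from a participant-level random-intercept model
  (shared intercept + residual noise), clipped to the value-set range;
* right-skewed resource use: negative-binomial visit counts and
  sick-leave days, gamma-distributed domestic-work cutback hours, and a
  persistent per-participant unemployment flag;
* missingness applied per instrument (diagnostic interview, EQ-5D,
  TIC-P) with arm x timepoint completion rates, optionally missing at
  random (MAR) through a logistic dependence on baseline utility whose
  intercept is solved numerically to hit the target marginal rate.

Default calibration targets the observed trial: remission 2%/32%
(control/intervention) at post and 9%/40% at follow-up; utility means
0.75/0.67/0.67 (control) and 0.71/0.73/0.80 (intervention); cost-item
rates solved from per-category USD means so that societal-perspective
cell means land near $4354/$4052/$3808 (control) and $4657/$5585/$5199
(intervention); completion rates per instrument as observed (e.g. 85%
follow-up diagnostic completion in the intervention arm).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .costing import TariffTable, RESOURCE_ITEMS

__all__ = [
    "TrialConfig",
    "generate_trial",
    "apply_missingness",
    "rates_from_category_means",
    "DEFAULT_CATEGORY_MEANS_USD",
    "INSTRUMENTS",
    "INSTRUMENT_COLUMNS",
]

ARMS = ("control", "intervention")
TIMEPOINTS = ("pre", "post", "followup")

#: instruments that can be independently missing, and the columns they carry
INSTRUMENT_COLUMNS = {
    "diagnostic": ("remission",),
    "eq5d": ("eq5d_index",),
    "ticp": RESOURCE_ITEMS,
}
INSTRUMENTS = tuple(INSTRUMENT_COLUMNS)

# Per-category USD means over the 12-week period, chosen so that with the
# default tariff the societal cell means sit near the observed trial's.
# health_care_excl_clinic is split 85% visits (50/30/20 primary/specialist/
# psychiatric) and 15% medication; indirect_excl_unemployment 75% sick
# leave, 25% domestic cutback.  Unemployment adds 0.20 x $3498 per cell.
DEFAULT_CATEGORY_MEANS_USD = {
    ("control", "pre"): {"health_care_excl_clinic": 1517.0, "indirect_excl_unemployment": 2137.4},
    ("control", "post"): {"health_care_excl_clinic": 1001.0, "indirect_excl_unemployment": 1890.4},
    ("control", "followup"): {"health_care_excl_clinic": 1193.0, "indirect_excl_unemployment": 1915.4},
    ("intervention", "pre"): {"health_care_excl_clinic": 1262.0, "indirect_excl_unemployment": 2695.4},
    ("intervention", "post"): {"health_care_excl_clinic": 1297.0, "indirect_excl_unemployment": 2642.4},
    ("intervention", "followup"): {"health_care_excl_clinic": 2346.0, "indirect_excl_unemployment": 2153.4},
}

_VISIT_SHARES = {
    "primary_care_visits": 0.85 * 0.50,
    "specialist_visits": 0.85 * 0.30,
    "psychiatric_visits": 0.85 * 0.20,
    "medication_units": 0.15,
}
_INDIRECT_SHARES = {"sick_leave_days": 0.75, "domestic_cutback_hours": 0.25}


def rates_from_category_means(
    category_means: dict, tariff: TariffTable | None = None
) -> dict:
    """Convert per-cell category USD targets into mean item counts.

    Returns ``{item: {(arm, timepoint): mean count per 4-week recall}}``.
    Counts divide the category dollars by the tariff's full-period USD
    price per recall-window unit, so the costing stage reproduces the
    targets in expectation.
    """
    tariff = tariff or TariffTable()
    rates: dict[str, dict[tuple[str, str], float]] = {
        item: {} for item in list(_VISIT_SHARES) + list(_INDIRECT_SHARES)
    }
    for cell, targets in category_means.items():
        for item, share in _VISIT_SHARES.items():
            rates[item][cell] = (
                targets["health_care_excl_clinic"] * share / tariff.usd_per_unit(item)
            )
        for item, share in _INDIRECT_SHARES.items():
            rates[item][cell] = (
                targets["indirect_excl_unemployment"]
                * share
                / tariff.usd_per_unit(item)
            )
    return rates


def _default_remission() -> dict:
    return {
        "control": {"post": 0.02, "followup": 0.09},
        "intervention": {"post": 0.32, "followup": 0.40},
    }


def _default_utility() -> dict:
    return {
        "control": {"pre": 0.75, "post": 0.67, "followup": 0.67},
        "intervention": {"pre": 0.71, "post": 0.73, "followup": 0.80},
    }


def _default_completion() -> dict:
    # observed completion: all 94 post diagnostics; 40/47 = 85% and
    # 45/47 = 96% follow-up diagnostics; EQ-5D 96/100% post, 77/94% f-u;
    # TIC-P 96/98% post, 77/91% f-u (intervention/control)
    return {
        "diagnostic": {
            "control": {"post": 1.0, "followup": 0.96},
            "intervention": {"post": 1.0, "followup": 0.85},
        },
        "eq5d": {
            "control": {"post": 1.0, "followup": 0.94},
            "intervention": {"post": 0.96, "followup": 0.77},
        },
        "ticp": {
            "control": {"post": 0.98, "followup": 0.91},
            "intervention": {"post": 0.96, "followup": 0.77},
        },
    }


@dataclass
class TrialConfig:
    """Generating parameters of the synthetic trial."""

    n_per_arm: int = 47
    timepoints: tuple = TIMEPOINTS
    remission_prob: dict = field(default_factory=_default_remission)
    utility_mean: dict = field(default_factory=_default_utility)
    utility_sd: float = 0.14
    random_intercept_sd: float = 0.18
    utility_range: tuple = (-0.59, 1.0)
    cost_item_rates: dict | None = None  # None -> default Table-style calibration
    cost_category_means: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_CATEGORY_MEANS_USD)
    )
    nb_dispersion: float = 1.5
    gamma_shape: float = 1.2
    cost_frailty_cv: float = 0.5  # per-participant cost propensity (CV; 0 disables)
    unemployment_prob: float = 0.20
    completion_rate: dict = field(default_factory=_default_completion)
    mar_strength: float = -3.0  # logit slope on baseline utility; 0 => MCAR
    heteroscedastic: float = 0.0  # >0 inflates residual SD in low-utility cells
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm <= 0:
            raise ValueError(f"n_per_arm must be positive, got {self.n_per_arm}")
        if len(self.timepoints) < 2 or len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("timepoints must be distinct ordered labels")
        for arm, probs in self.remission_prob.items():
            for tp, p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"remission_prob[{arm}][{tp}]={p} outside [0,1]")
        if not 0 <= self.unemployment_prob <= 1:
            raise ValueError("unemployment_prob outside [0,1]")
        for sd_name in ("utility_sd", "random_intercept_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be nonnegative")
        lo, hi = self.utility_range
        for arm, means in self.utility_mean.items():
            for tp, m in means.items():
                if not lo <= m <= hi:
                    raise ValueError(f"utility_mean[{arm}][{tp}]={m} outside value-set range")
        for inst, by_arm in self.completion_rate.items():
            for arm, by_tp in by_arm.items():
                for tp, cr in by_tp.items():
                    if not 0 <= cr <= 1:
                        raise ValueError(
                            f"completion_rate[{inst}][{arm}][{tp}]={cr} outside [0,1]"
                        )

    def resolved_rates(self, tariff: TariffTable | None = None) -> dict:
        if self.cost_item_rates is not None:
            return self.cost_item_rates
        return rates_from_category_means(self.cost_category_means, tariff)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["timepoints"] = list(d["timepoints"])
        d["utility_range"] = list(d["utility_range"])
        d["cost_category_means"] = {
            f"{arm}:{tp}": v for (arm, tp), v in d["cost_category_means"].items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrialConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["timepoints"] = tuple(d["timepoints"])
        d["utility_range"] = tuple(d["utility_range"])
        d["cost_category_means"] = {
            tuple(k.split(":")): v for k, v in d["cost_category_means"].items()
        }
        return cls(**d)


def _clipped_normal_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    """Mean of clip(N(mu, sd^2), lo, hi)."""
    from scipy.stats import norm

    a, b = (lo - mu) / sd, (hi - mu) / sd
    return (
        lo * norm.cdf(a)
        + hi * norm.sf(b)
        + mu * (norm.cdf(b) - norm.cdf(a))
        - sd * (norm.pdf(b) - norm.pdf(a))
    )


def _location_for_clipped_mean(
    target: float, sd: float, lo: float, hi: float
) -> float:
    """Pre-clipping location whose clipped-normal mean equals *target*,
    so that clipping to the value-set range leaves cell means calibrated."""
    if sd == 0:
        return target
    return brentq(
        lambda mu: _clipped_normal_mean(mu, sd, lo, hi) - target,
        lo - 10 * sd,
        hi + 10 * sd,
    )


def _nb_draw(rng, mean: np.ndarray, k: float) -> np.ndarray:
    """Negative binomial with mean `mean` and dispersion `k` (var = m + m^2/k)."""
    mean = np.asarray(mean, float)
    p = k / (k + mean)
    return rng.negative_binomial(k, p).astype(float)


def generate_trial(
    config: TrialConfig | None = None,
    *,
    tariff: TariffTable | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a complete participant x timepoint table.

    One row per participant per timepoint; 2 x ``n_per_arm``
    participants.  Fully reproducible from the seed (argument overrides
    ``config.seed``).  Missingness is applied separately by
    :func:`apply_missingness`.
    """
    config = config or TrialConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rates = config.resolved_rates(tariff)
    n = config.n_per_arm
    lo, hi = config.utility_range

    frames = []
    for arm in ARMS:
        pids = [f"{arm[0].upper()}{i:04d}" for i in range(n)]
        intercepts = rng.normal(0.0, config.random_intercept_sd, size=n)
        unemployed = (rng.random(n) < config.unemployment_prob).astype(float)
        if config.cost_frailty_cv > 0:
            # shared high/low-consumer propensity; mean 1 preserves cell means
            shape = 1.0 / config.cost_frailty_cv**2
            frailty = rng.gamma(shape, 1.0 / shape, size=n)
        else:
            frailty = np.ones(n)
        for tp in config.timepoints:
            mu = config.utility_mean[arm][tp]
            resid_sd = config.utility_sd * (
                1.0 + config.heteroscedastic * max(0.0, 1.0 - mu)
            )
            total_sd = float(np.hypot(config.random_intercept_sd, resid_sd))
            mu_adj = _location_for_clipped_mean(mu, total_sd, lo, hi)
            utility = mu_adj + intercepts + rng.normal(0.0, resid_sd, size=n)
            utility = np.clip(utility, lo, hi)
            if tp == "pre":
                remission = np.full(n, np.nan)
            else:
                remission = (
                    rng.random(n) < config.remission_prob[arm][tp]
                ).astype(float)
            row = {
                "participant_id": pids,
                "arm": arm,
                "timepoint": tp,
                "remission": remission,
                "eq5d_index": utility,
                "unemployed": unemployed,
            }
            for item in (
                "primary_care_visits",
                "specialist_visits",
                "psychiatric_visits",
                "medication_units",
                "sick_leave_days",
            ):
                m = rates[item][(arm, tp)] * frailty
                row[item] = _nb_draw(rng, m, config.nb_dispersion)
            gm = rates["domestic_cutback_hours"][(arm, tp)] * frailty
            row["domestic_cutback_hours"] = rng.gamma(
                config.gamma_shape, gm / config.gamma_shape
            )
            frames.append(pd.DataFrame(row))

    table = pd.concat(frames, ignore_index=True)
    order = ["participant_id", "arm", "timepoint", "remission", "eq5d_index"] + list(
        RESOURCE_ITEMS
    )
    table = table[order]
    table["timepoint"] = pd.Categorical(
        table["timepoint"], categories=list(config.timepoints), ordered=True
    )
    return table.sort_values(["arm", "participant_id", "timepoint"]).reset_index(
        drop=True
    )


def _solve_mar_intercept(u0: np.ndarray, slope: float, target_missing: float) -> float:
    """Intercept a such that mean(expit(a + slope*(u0 - mean(u0)))) = target."""
    if target_missing <= 0:
        return -np.inf
    if target_missing >= 1:
        return np.inf
    centred = u0 - u0.mean()

    def gap(a):
        return expit(a + slope * centred).mean() - target_missing

    return brentq(gap, -30.0, 30.0)


def apply_missingness(
    table: pd.DataFrame,
    config: TrialConfig | None = None,
    *,
    seed: int | None = None,
) -> pd.DataFrame:
    """Blank out instrument values according to the completion rates.

    Per instrument and arm x timepoint, values are set missing with
    probability ``1 - completion_rate``.  With ``mar_strength != 0`` the
    missingness probability depends on the participant's *baseline*
    (observed) utility through a logistic model whose intercept is
    solved to preserve the marginal rate — a MAR mechanism: given
    baseline utility, missingness is independent of the unobserved
    value.  Pre-treatment records are never made missing.
    """
    config = config or TrialConfig()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    out = table.copy()

    base = (
        table[table["timepoint"] == "pre"]
        .set_index("participant_id")["eq5d_index"]
    )

    for inst in INSTRUMENTS:
        by_arm = config.completion_rate.get(inst, {})
        for arm in ARMS:
            for tp in config.timepoints:
                if tp == "pre":
                    continue
                cr = by_arm.get(arm, {}).get(tp, 1.0)
                if cr >= 1.0:
                    continue
                mask = (out["arm"] == arm) & (out["timepoint"] == tp)
                idx = out.index[mask]
                u0 = base.loc[out.loc[idx, "participant_id"]].to_numpy(float)
                if config.mar_strength != 0.0:
                    a = _solve_mar_intercept(u0, config.mar_strength, 1.0 - cr)
                    p_miss = expit(a + config.mar_strength * (u0 - u0.mean()))
                else:
                    p_miss = np.full(len(idx), 1.0 - cr)
                drop = rng.random(len(idx)) < p_miss
                cols = list(INSTRUMENT_COLUMNS[inst])
                out.loc[idx[drop], cols] = np.nan
    return out


def write_trial_csv(table: pd.DataFrame, path) -> None:
    """Write the participant table as CSV with missing values as empty fields."""
    table.to_csv(path, index=False)


def read_trial_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    tps = [t for t in TIMEPOINTS if t in set(table["timepoint"])]
    table["timepoint"] = pd.Categorical(table["timepoint"], categories=tps, ordered=True)
    return table
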