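"""Pipeline orchestration and report bundles.

:func:`run_pipeline` drives the full analysis from a :class:`RunConfig`
(either a participant CSV or simulate-mode generation), writes the
descriptive table, ICER table, CEAC curves, quadrant JSON and the two
sensitivity variants, and records seed, replicate count and software
versions in a run log.  Outputs are byte-stable given the same config
and seed.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import sensitivity
from .costing import TariffTable
from .model import CostEffectivenessModel
from .outcomes import ValueSet
from .simulate import TrialConfig

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one analysis run needs."""

    participants_csv: str | None = None  # None -> simulate
    tariff_csv: str | None = None
    value_set_csv: str | None = None
    trial_config: TrialConfig | None = None
    bootstrap_reps: int = 1000
    bootstrap_method: str = "mixed"
    seed: int = 0
    lambda_max: float = 60000.0
    lambda_step: float = 1000.0
    perspectives: tuple = ("clinic", "health_care", "societal")
    run_sensitivity: bool = True
    outdir: str = "trialcea_out"

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "trial_config" in d and d["trial_config"] is not None:
            d["trial_config"] = TrialConfig(**d["trial_config"])
        if "perspectives" in d:
            d["perspectives"] = tuple(d["perspectives"])
        return cls(**d)


def _build_model(config: RunConfig) -> CostEffectivenessModel:
    tariff = TariffTable.from_csv(config.tariff_csv) if config.tariff_csv else None
    vs = ValueSet.from_csv(config.value_set_csv) if config.value_set_csv else None
    grid = np.arange(0.0, config.lambda_max + config.lambda_step / 2, config.lambda_step)
    if config.participants_csv:
        return CostEffectivenessModel.from_csv(
            config.participants_csv,
            tariff_csv=config.tariff_csv,
            value_set_csv=config.value_set_csv,
            perspectives=config.perspectives,
            lambda_grid=grid,
        )
    return CostEffectivenessModel.simulate(
        config.trial_config or TrialConfig(),
        seed=config.seed,
        tariff=tariff,
        value_set=vs,
        perspectives=config.perspectives,
        lambda_grid=grid,
    )


def run_pipeline(config: RunConfig, *, log=sys.stderr) -> dict:
    """Run the full cost-effectiveness pipeline and write the bundle.

    Returns ``{"base": CEAResults, ...}`` with sensitivity variants when
    requested; files land under ``config.outdir`` (variant-labelled).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = _build_model(config)

    def _say(msg):
        if log is not None:
            print(f"[trialcea] {msg}", file=log)

    _say(
        f"base run: {model.data['participant_id'].nunique()} participants, "
        f"B={config.bootstrap_reps}, seed={config.seed}"
    )
    results = {}
    res = model.fit(
        bootstrap_reps=config.bootstrap_reps,
        seed=config.seed,
        bootstrap_method=config.bootstrap_method,
    )
    res.save(outdir / "base", variant="base")
    results["base"] = res

    if config.run_sensitivity:
        _say("sensitivity: complete cases")
        cc_model = CostEffectivenessModel(
            model.raw_data,
            tariff=model.tariff,
            perspectives=model.perspectives,
            lambda_grid=model.lambda_grid,
            complete_case=True,
        )
        cc_res = cc_model.fit(
            bootstrap_reps=config.bootstrap_reps,
            seed=config.seed,
            bootstrap_method=config.bootstrap_method,
        )
        cc_res.save(outdir / "complete_case", variant="complete_case")
        results["complete_case"] = cc_res

        _say("sensitivity: societal costs excluding unemployment")
        ex_res = sensitivity.run_excluding_unemployment(
            model,
            bootstrap_reps=config.bootstrap_reps,
            seed=config.seed,
            bootstrap_method=config.bootstrap_method,
        )
        ex_res.save(outdir / "exclude_unemployment", variant="exclude_unemployment")
        results["exclude_unemployment"] = ex_res

    _say("done")
    return results
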