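"""Configuration models (pydantic) and YAML/JSON loading."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator


class Hyperprior(BaseModel):
    """Truncated-normal hyperprior for one per-participant parameter."""

    mean: float
    sd: float = Field(ge=0)
    low: float = float("-inf")
    high: float = float("inf")

    @model_validator(mode="after")
    def _check(self):
        if not self.low < self.high:
            raise ValueError("hyperprior requires low < high")
        return self


# Cohort-level defaults.  Rating scale is [0, 1]; drift/threshold are in the
# per-millisecond evidence units used by the simulators, chosen so that a
# typical trial (|dV| ~ 0.2) crosses the bound in roughly 1-3 s and choice
# consistency sits in the empirically usual 70-95% band.
_DEFAULT_HYPERPRIORS = {
    "drift": Hyperprior(mean=0.065, sd=0.013, low=0.016, high=0.26),
    "drift_p": Hyperprior(mean=0.045, sd=0.011, low=0.009, high=0.18),
    "drift_n": Hyperprior(mean=0.019, sd=0.0095, low=0.004, high=0.076),
    "threshold": Hyperprior(mean=65.0, sd=11.0, low=32.0, high=130.0),
    # separate bound for the multi-attribute kinds: their difference-process
    # noise is doubled, so the bound scales ~sqrt(2) to match deliberation
    # timescales (parameters are model-specific in a per-model fit)
    "threshold_ma": Hyperprior(mean=90.0, sd=15.0, low=45.0, high=180.0),
    "ndt": Hyperprior(mean=0.4, sd=0.1, low=0.1, high=0.9),
    "start_p": Hyperprior(mean=0.0, sd=0.0, low=0.0, high=0.9),
    "start_n": Hyperprior(mean=0.3, sd=0.15, low=0.0, high=0.9),
}


class CohortConfig(BaseModel):
    """Generator settings for a synthetic rating-and-choice cohort."""

    n_participants: int = Field(default=50, ge=1)
    n_options: int = Field(default=120, ge=4)
    rating_noise_sd: float = Field(default=0.1, ge=0)
    attr_weight_p: Hyperprior = Hyperprior(mean=0.6, sd=0.15, low=0.05, high=1.5)
    attr_weight_n: Hyperprior = Hyperprior(mean=0.4, sd=0.15, low=0.05, high=1.5)
    attr_correlation: float = Field(default=-0.3, ge=-1.0, le=1.0)
    param_hyperpriors: dict[str, Hyperprior] = Field(
        default_factory=lambda: dict(_DEFAULT_HYPERPRIORS)
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.n_options % 2 != 0:
            raise ValueError("n_options must be even: pairing consumes all options")
        missing = set(_DEFAULT_HYPERPRIORS) - set(self.param_hyperpriors)
        if missing:
            merged = dict(_DEFAULT_HYPERPRIORS)
            merged.update(self.param_hyperpriors)
            self.param_hyperpriors = merged
        return self


class FitConfig(BaseModel):
    """MAP-fitting settings."""

    n_starts: int = Field(default=3, ge=1)
    prior_scale: float = Field(default=1.0, gt=0)
    loglik_floor: float = Field(default=-27.63, lt=0)  # log(1e-12)
    maxiter: int = Field(default=500, ge=10)
    grid_dt_ms: float = Field(default=0.25, gt=0)
    grid_dx: float = Field(default=0.15, gt=0)


class AnalyzeConfig(BaseModel):
    n_quantile_bins: int = Field(default=5, ge=2)
    multiple_testing: Literal["none", "bonferroni"] = "none"


class PipelineConfig(BaseModel):
    """End-to-end run settings."""

    cohort: CohortConfig = CohortConfig()
    fit: FitConfig = FitConfig()
    analyze: AnalyzeConfig = AnalyzeConfig()
    models: list[Literal["ddm", "maddm", "stddm"]] = ["ddm", "maddm", "stddm"]
    use_fitted_params: bool = False
    seed: int = 0
    out_dir: str = "driftspread_out"


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig.model_validate(data)
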