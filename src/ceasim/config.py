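"""Configuration schema, serialization and the end-to-end pipeline.

A run configuration is one YAML document holding the use case, run-level
settings (seed, replicate counts, discount rate, WTP grid), the flat model
parameter table, and the PSA distribution blocks.  Unknown keys are
rejected; defaults are filled in and recorded, so a saved configuration
plus its manifest reproduce any run bit-identically.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import List, Literal, Optional, Sequence, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .economics import ceac, icer
from .psa import (ParameterDistribution, PSAResult, find_threshold,
                  one_way_sweep, run_psa, evaluate_point)
from .synthetic import ParamSet
from .use_cases import USE_CASES, Scenario

__all__ = [
    "DistributionConfig",
    "RunConfig",
    "RunManifest",
    "PipelineResult",
    "load_config",
    "save_config",
    "config_from_paramset",
    "scenario_from_config",
    "distributions_from_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: flat parameter keys with these prefixes must be probabilities/utilities
_PROB_PREFIXES = ("p_", "u_", "sens_", "spec_", "prevalence_", "rr_")


class DistributionConfig(BaseModel):
    """One PSA uncertainty block (see :class:`~ceasim.psa.ParameterDistribution`)."""

    model_config = ConfigDict(extra="forbid")

    name: str
    family: Literal["beta", "gamma", "uniform", "fixed"]
    mean: Optional[float] = None
    ci: Optional[List[float]] = None
    low: Optional[float] = None
    high: Optional[float] = None
    bounds: Optional[List[Optional[float]]] = None

    def to_distribution(self) -> ParameterDistribution:
        bounds = None
        if self.bounds is not None:
            lo = -np.inf if self.bounds[0] is None else self.bounds[0]
            hi = np.inf if self.bounds[1] is None else self.bounds[1]
            bounds = (lo, hi)
        return ParameterDistribution(
            self.name, self.family, mean=self.mean,
            ci=tuple(self.ci) if self.ci else None,
            low=self.low, high=self.high, bounds=bounds)


class RunConfig(BaseModel):
    """Schema-validated full run configuration with explicit defaults."""

    model_config = ConfigDict(extra="forbid")

    use_case: Literal["dermatology", "dentistry", "ophthalmology"]
    synthetic: bool = True
    seed: int = Field(default=0, ge=0, lt=2 ** 31)
    n_psa: int = Field(default=1000, ge=1)
    n_individuals: int = Field(default=1000, ge=1)
    discount_rate: float = Field(default=0.03, ge=0.0, le=1.0)
    discount_effects: bool = True
    currency: Literal["USD", "EUR", "BRL"] = "USD"
    wtp_max: float = Field(default=100_000.0, gt=0.0)
    wtp_step: float = Field(default=1000.0, gt=0.0)
    params: dict
    distributions: List[DistributionConfig] = []

    @field_validator("params")
    @classmethod
    def _check_params(cls, params: dict) -> dict:
        for key, value in params.items():
            if key.startswith(_PROB_PREFIXES) and np.isscalar(value):
                if not 0.0 <= float(value) <= 1.0:
                    raise ValueError(
                        f"params[{key!r}] = {value} must lie in [0, 1]")
            if key == "background_mortality":
                table = np.asarray(value, dtype=float)
                if np.any((table < 0) | (table > 1)):
                    raise ValueError(
                        "params['background_mortality'] entries must lie "
                        "in [0, 1]")
        return params

    def wtp_grid(self) -> np.ndarray:
        return np.arange(0.0, self.wtp_max + self.wtp_step / 2,
                         self.wtp_step)


def load_config(path) -> RunConfig:
    """Read and schema-validate a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a YAML mapping at top level")
    return RunConfig.model_validate(raw)


def _canonical_dict(cfg: RunConfig) -> dict:
    data = cfg.model_dump(mode="json")
    params = {}
    for key, value in data["params"].items():
        if isinstance(value, np.ndarray):
            value = value.tolist()
        params[key] = value
    data["params"] = params
    return data


def save_config(cfg: RunConfig, path) -> None:
    """Write a configuration as YAML (UTF-8, period decimal separator)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_canonical_dict(cfg), fh, sort_keys=True,
                       allow_unicode=True)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(_canonical_dict(cfg), sort_keys=True)
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()


def config_from_paramset(pset: ParamSet, **overrides) -> RunConfig:
    """Wrap a synthetic parameter set into a run configuration."""
    params = {}
    for key, value in pset.params.items():
        if isinstance(value, np.ndarray):
            value = [float(v) for v in value]
        params[key] = value
    dists = []
    for d in pset.distributions:
        bounds = None
        if d.bounds is not None:
            bounds = [None if not np.isfinite(b) else float(b)
                      for b in d.bounds]
        dists.append(DistributionConfig(
            name=d.name, family=d.family, mean=d.mean,
            ci=list(d.ci) if d.ci else None, low=d.low, high=d.high,
            bounds=bounds))
    defaults = dict(use_case=pset.use_case, synthetic=pset.synthetic,
                    seed=pset.seed,
                    currency={"dermatology": "USD", "dentistry": "EUR",
                              "ophthalmology": "BRL"}[pset.use_case],
                    params=params, distributions=dists)
    defaults.update(overrides)
    return RunConfig(**defaults)


def scenario_from_config(cfg: RunConfig) -> Scenario:
    params = dict(cfg.params)
    if "background_mortality" in params:
        params["background_mortality"] = np.asarray(
            params["background_mortality"], dtype=float)
    params.pop("synthetic", None)
    return USE_CASES[cfg.use_case](
        params, discount_rate=cfg.discount_rate,
        discount_effects=cfg.discount_effects)


def distributions_from_config(cfg: RunConfig):
    return [d.to_distribution() for d in cfg.distributions]


@dataclass
class RunManifest:
    """Provenance of one run: everything needed to reproduce it."""

    config_hash: str
    master_seed: int
    n_psa: int
    n_individuals: int
    discount_rate: float
    package_version: str
    created_utc: str

    @classmethod
    def for_run(cls, cfg: RunConfig) -> "RunManifest":
        return cls(config_hash(cfg), cfg.seed, cfg.n_psa, cfg.n_individuals,
                   cfg.discount_rate, __version__,
                   datetime.now(timezone.utc).isoformat(timespec="seconds"))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    """Bundle returned by :func:`run_pipeline`."""

    psa: PSAResult
    ceac_curve: "object"
    sweeps: dict
    thresholds: dict
    manifest: RunManifest


def run_pipeline(cfg: RunConfig, out_dir=None,
                 sweep_names: Sequence[str] = ("discount_rate", "fee"),
                 sweep_n: int = 1000) -> PipelineResult:
    """PSA → economics → CEAC → one-way sweeps, with CSV/manifest output.

    Stage failures abort with the stage named in the raised error.
    """
    scenario = scenario_from_config(cfg)
    manifest = RunManifest.for_run(cfg)
    stages = {}
    try:
        stage = "psa"
        psa_result = run_psa(scenario, distributions_from_config(cfg),
                             n_psa=cfg.n_psa,
                             n_individuals=cfg.n_individuals,
                             master_seed=cfg.seed)
        stage = "ceac"
        curve = ceac(psa_result.draws, cfg.wtp_grid())
        stage = "sweeps"
        sweeps = {}
        thresholds = {}
        for name in sweep_names:
            table = one_way_sweep(scenario, name, seed=cfg.seed,
                                  n_individuals=sweep_n)
            sweeps[name] = table

            def _evaluator(value, _name=name):
                pair = evaluate_point(scenario, _name, value, cfg.seed,
                                      sweep_n)
                return pair.delta_cost

            thresholds[name] = find_threshold(table, evaluator=_evaluator)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        psa_result.draws.to_csv(out / "ce_draws.csv")
        psa_result.summary.to_csv(out / "summary.csv", index=False)
        curve.to_csv(out / "ceac.csv")
        for name, table in sweeps.items():
            table.to_csv(out / f"sweep_{name}.csv", index=False)
        manifest.to_json(out / "manifest.json")
        save_config(cfg, out / "config.yaml")
        logger.info("pipeline outputs written to %s", out)
    return PipelineResult(psa_result, curve, sweeps, thresholds, manifest)
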