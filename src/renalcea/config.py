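"""Configuration loading and validation.

A single YAML (or JSON) file is the only entry point for model parameters;
the shipped default configuration carries the published base case. Loading
validates every typed input's invariants via pydantic and produces a run
manifest so two runs from the same manifest are reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import __version__
from .calibration import WeibullParams, apply_hazard_ratio
from .costs import CostInputs
from .markov import ModelSettings, TransitionSet
from .psa import PARAMETER_NAMES, ParameterRange

__all__ = ["AppConfig", "RunManifest", "load_config", "default_config_path", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or incomplete model configuration."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    n_cycles: int = Field(ge=1)
    cycle_length: float = Field(gt=0)
    discount_rate: float = Field(ge=0)
    cohort_size: int = Field(ge=1)
    utility_ckd: float = Field(ge=0, le=1)
    utility_dialysis: float = Field(ge=0, le=1)
    wtp_per_capita_gdp: float = Field(ge=0)


class CurveSection(_Strict):
    lam: float = Field(gt=0)
    gamma: float = Field(gt=0)
    hazard_ratio_rhp: float = Field(gt=0)


class SurvivalSection(_Strict):
    dialysis: CurveSection
    death: CurveSection
    dialysis_to_death: float = Field(ge=0, le=1)


class CostsSection(_Strict):
    rhp_treatment_annual: float = Field(ge=0)
    soc_treatment_annual: float = Field(ge=0)
    dialysis_annual: float = Field(ge=0)
    rhp_initial: float = Field(ge=0)
    rhp_operational_annual: float = Field(ge=0)


class RangeSection(_Strict):
    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self):
        if self.low > self.high:
            raise ValueError("low must be <= high")
        return self


class PSASection(_Strict):
    n_iterations: int = Field(ge=1)
    seed: int  # mandatory: PSA runs must be reproducible
    ranges: dict[str, RangeSection]

    @model_validator(mode="after")
    def _known_names(self):
        unknown = set(self.ranges) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown PSA parameter(s): {sorted(unknown)}")
        return self


class ThresholdSection(_Strict):
    bracket: tuple[float, float] = (0.0, 20_000.0)
    tolerance: float = Field(default=0.005, gt=0)


class AppConfig(_Strict):
    """Validated full model configuration."""

    model: ModelSection
    survival: SurvivalSection
    costs: CostsSection
    psa: PSASection
    threshold: ThresholdSection = ThresholdSection()

    # -- builders for the typed engine inputs -------------------------------

    def settings(self) -> ModelSettings:
        return ModelSettings(**self.model.model_dump())

    def cost_inputs(self) -> CostInputs:
        return CostInputs(cohort_size=self.model.cohort_size, **self.costs.model_dump())

    def transitions(self, arm: str) -> TransitionSet:
        s = self.survival
        dial = WeibullParams(s.dialysis.lam, s.dialysis.gamma)
        death = WeibullParams(s.death.lam, s.death.gamma)
        if arm == "rhp":
            dial = apply_hazard_ratio(dial, s.dialysis.hazard_ratio_rhp)
            death = apply_hazard_ratio(death, s.death.hazard_ratio_rhp)
        elif arm != "soc":
            raise ConfigError(f"arm must be 'rhp' or 'soc', got {arm!r}")
        return TransitionSet(
            ckd_to_dialysis=dial, ckd_to_death=death, dialysis_to_death=s.dialysis_to_death
        )

    def parameter_ranges(self) -> list[ParameterRange]:
        """PSA ranges; parameters without a configured range are held fixed."""
        bases = {
            "hr_dialysis": self.survival.dialysis.hazard_ratio_rhp,
            "hr_death": self.survival.death.hazard_ratio_rhp,
            "lambda_dialysis": self.survival.dialysis.lam,
            "gamma_dialysis": self.survival.dialysis.gamma,
            "lambda_death": self.survival.death.lam,
            "gamma_death": self.survival.death.gamma,
            "rhp_treatment_annual": self.costs.rhp_treatment_annual,
            "soc_treatment_annual": self.costs.soc_treatment_annual,
            "dialysis_annual": self.costs.dialysis_annual,
            "utility_ckd": self.model.utility_ckd,
            "utility_dialysis": self.model.utility_dialysis,
            "discount_rate": self.model.discount_rate,
        }
        out = []
        for name in PARAMETER_NAMES:
            base = bases[name]
            rng = self.psa.ranges.get(name)
            if rng is None:
                out.append(ParameterRange(name, base, base, base, sampling="fixed"))
            else:
                out.append(ParameterRange(name, base, rng.low, rng.high))
        return out

    def resolved_parameters(self) -> dict:
        """Flat parameter table for the run manifest."""
        flat: dict = {}
        for section, dump in (
            ("model", self.model.model_dump()),
            ("survival.dialysis", self.survival.dialysis.model_dump()),
            ("survival.death", self.survival.death.model_dump()),
            ("survival", {"dialysis_to_death": self.survival.dialysis_to_death}),
            ("costs", self.costs.model_dump()),
        ):
            for k, v in dump.items():
                flat[f"{section}.{k}"] = v
        return flat


@dataclass(frozen=True)
class RunManifest:
    """Provenance record of one pipeline run."""

    config_sha256: str
    resolved_parameters: dict
    software_version: str
    seeds: dict
    created_utc: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def default_config_path() -> Path:
    return Path(resources.files("renalcea") / "data" / "default_config.yaml")


def load_config(path: str | Path | None = None) -> tuple[AppConfig, RunManifest]:
    """Load and validate a YAML/JSON config; None loads the shipped default.

    Raises :class:`ConfigError` naming the offending key on any missing or
    out-of-domain value.
    """
    p = Path(path) if path is not None else default_config_path()
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    text = p.read_text()
    try:
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {p}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        cfg = AppConfig.model_validate(raw)
    except ValidationError as exc:
        issues = "; ".join(
            f"{'.'.join(str(loc) for loc in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"invalid configuration in {p}: {issues}") from exc
    manifest = RunManifest(
        config_sha256=hashlib.sha256(text.encode()).hexdigest(),
        resolved_parameters=cfg.resolved_parameters(),
        software_version=__version__,
        seeds={"psa": cfg.psa.seed},
        created_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    return cfg, manifest
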