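"""Synthetic competing-risk cohorts for exercising the survival calibration.

The registry behind the original survival curves is not public, so this
module generates cohorts with the exact statistical structure the
calibration assumes: each subject carries two independent latent Weibull
event times — one to dialysis initiation, one to death — and the observed
record is the minimum of the two and an administrative censoring horizon
(a fixed study window; no random loss to follow-up). Under this
latent-failure-time construction the cause-specific hazards are the Weibull
hazards of the latent times, which is precisely what the downstream
Markov transition probabilities are built from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import WeibullParams

__all__ = ["EVENT_TYPES", "SubjectRecord", "GeneratorConfig", "generate_cohort",
           "write_cohort", "read_cohort"]

EVENT_TYPES = ("dialysis", "death", "censored")

#: Observation time assigned when the censoring horizon is exactly zero
#: (times must stay strictly positive).
_ZERO_HORIZON_EPS = 1e-9


@dataclass(frozen=True)
class SubjectRecord:
    """Row schema of a generated cohort: follow-up time (years) and event label."""

    time: float
    event: str

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"time must be positive, got {self.time}")
        if self.event not in EVENT_TYPES:
            raise ValueError(f"event must be one of {EVENT_TYPES}, got {self.event!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Inputs for one synthetic cohort draw; the seed is mandatory."""

    n_subjects: int
    dialysis_params: WeibullParams
    death_params: WeibullParams
    censor_horizon: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1 (empty cohorts are not generable)")
        if self.censor_horizon < 0:
            raise ValueError(f"censor_horizon must be >= 0, got {self.censor_horizon}")


def _sample_weibull(rng: np.random.Generator, params: WeibullParams, n: int) -> np.ndarray:
    # Inverse-CDF draw for S(t) = exp(-lam * t**gamma):  t = (E/lam)**(1/gamma)
    e = rng.exponential(size=n)
    return (e / params.lam) ** (1.0 / params.gamma)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a cohort table with columns ``time`` and ``event``.

    The observed record per subject is the minimum of the two latent event
    times and the censoring horizon; a horizon of exactly 0 censors every
    subject at an epsilon time. Identical configs (including seed) return
    identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    t_dial = _sample_weibull(rng, config.dialysis_params, n)
    t_death = _sample_weibull(rng, config.death_params, n)

    if config.censor_horizon == 0:
        return pd.DataFrame({"time": np.full(n, _ZERO_HORIZON_EPS), "event": "censored"})

    time = np.minimum(np.minimum(t_dial, t_death), config.censor_horizon)
    event = np.where(
        time >= config.censor_horizon,
        "censored",
        # ties between latent times have probability zero; dialysis wins by
        # the canonical event ordering if one ever occurs
        np.where(t_dial <= t_death, "dialysis", "death"),
    )
    return pd.DataFrame({"time": time, "event": event})


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as delimited text (CSV with header ``time,event``)."""
    cohort.to_csv(path, index=False, columns=["time", "event"])


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the schema and basic invariants."""
    df = pd.read_csv(path)
    missing = {"time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort file {path} lacks required column(s) {sorted(missing)}")
    if not (df["time"] > 0).all():
        raise ValueError("cohort contains non-positive observation times")
    bad = set(df["event"].unique()) - set(EVENT_TYPES)
    if bad:
        raise ValueError(f"cohort contains unknown event labels {sorted(bad)}")
    return df[["time", "event"]]
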