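"""Synthetic development-rate observations and GCM-like temperature ensembles.

The observation generator reproduces how literature development-time means
arise: cohorts of individuals are simulated at each constant temperature
with truncated-normal stage rates (standard deviation proportional to the
mean, coefficient of variation ``cv``), individual stage times are the
inverses of the rates, and the recorded observation is the cohort's mean
time. Optional per-study multiplicative offsets inject a study effect.
Temperature × stage combinations where the true curve predicts no
development yield no observation (real studies report no time there).

The ensemble generator is deliberately simple plumbing — a monthly
baseline, one warming offset per scenario, one once-per-GCM shift, and
interannual noise — enough to exercise the impact pipeline's schema and
statistics, not a climate emulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .climate import CURRENT_PERIOD, FUTURE_PERIOD, ENSEMBLE_COLUMNS, PeriodSpec
from .errors import ConfigurationError
from .fitting import RateObservation
from .models import TPCParameterSet, evaluate_rate
from .simulate import _truncated_normal

logger = logging.getLogger(__name__)

__all__ = [
    "ObservationGeneratorConfig",
    "EnsembleGeneratorConfig",
    "generate_observations",
    "generate_stage_observations",
    "generate_ensemble",
]


@dataclass(frozen=True)
class ObservationGeneratorConfig:
    """Conditions under which synthetic development-time means are produced.

    ``truth`` maps stage name → true curve. ``study_offsets`` multiplies
    the recorded mean development times of a study (1.0 = unbiased); one
    unbiased study "S1" is assumed when omitted.
    """

    truth: Mapping[str, TPCParameterSet]
    temperatures: Sequence[float]
    n_reps: int = 50
    cv: float = 0.15
    study_offsets: Mapping[str, float] = field(default_factory=lambda: {"S1": 1.0})
    species: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        if self.cv < 0:
            raise ConfigurationError("cv must be non-negative")
        for t in self.temperatures:
            if not 0.0 <= t <= 50.0:
                raise ConfigurationError(f"temperature {t} outside [0, 50] °C")


def generate_observations(config: ObservationGeneratorConfig) -> list[RateObservation]:
    """Simulate mean development times per study × temperature × stage.

    For each combination, ``n_reps`` individual rates are drawn from the
    truncated normal around the true curve rate, inverted to times, and
    averaged. Non-developing combinations (true rate 0) are omitted with a
    log line.
    """
    rng = np.random.default_rng(config.seed)
    out: list[RateObservation] = []
    for study_id, offset in config.study_offsets.items():
        for T in config.temperatures:
            for stage, params in config.truth.items():
                tau = evaluate_rate(params, float(T))
                if tau <= 0.0:
                    logger.info(
                        "no development for stage %s at %.1f °C (study %s): omitted",
                        stage, T, study_id,
                    )
                    continue
                if config.cv == 0.0:
                    mean_time = 1.0 / tau
                else:
                    rates = _truncated_normal(rng, tau, config.cv * tau, config.n_reps)
                    rates = rates[rates > 0.0]
                    if rates.size == 0:
                        continue
                    mean_time = float(np.mean(1.0 / rates))
                out.append(
                    RateObservation(
                        species=config.species,
                        stage=stage,
                        study_id=study_id,
                        temperature=float(T),
                        mean_dev_time=mean_time * float(offset),
                    )
                )
    return out


def generate_stage_observations(
    params: TPCParameterSet,
    temperatures: Sequence[float],
    n_reps: int = 50,
    cv: float = 0.15,
    seed: int = 0,
    stage: str = "larva",
    species: str = "synthetic",
) -> list[RateObservation]:
    """Single-stage shortcut used by parameter-recovery harnesses."""
    config = ObservationGeneratorConfig(
        truth={stage: params},
        temperatures=temperatures,
        n_reps=n_reps,
        cv=cv,
        species=species,
        seed=seed,
    )
    return generate_observations(config)


@dataclass(frozen=True)
class EnsembleGeneratorConfig:
    """Shift-plus-noise emulation of a regional monthly-temperature ensemble.

    Historical series are the baseline plus interannual noise; each future
    scenario adds its warming offset plus a once-per-GCM shift (spread
    ``inter_gcm_sd``) representing between-model disagreement. Default
    offsets are indicative end-of-century regional warmings for a low- and
    a high-emission pathway.
    """

    baseline_monthly: Sequence[float]  # 12 values, °C
    warming_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"ssp126": 1.5, "ssp585": 4.0}
    )
    n_gcms: int = 12
    inter_gcm_sd: float = 0.5
    interannual_sd: float = 0.5
    region: str = "SYN"
    current: PeriodSpec = CURRENT_PERIOD
    future: PeriodSpec = FUTURE_PERIOD
    seed: int = 0

    def __post_init__(self):
        if len(self.baseline_monthly) != 12:
            raise ConfigurationError("baseline_monthly must hold 12 values")
        if self.n_gcms < 1:
            raise ConfigurationError("n_gcms must be >= 1")
        if self.inter_gcm_sd < 0 or self.interannual_sd < 0:
            raise ConfigurationError("noise standard deviations must be non-negative")


def generate_ensemble(config: EnsembleGeneratorConfig) -> pd.DataFrame:
    """Flat ensemble table with columns region, scenario, gcm, year, month, tas_C."""
    rng = np.random.default_rng(config.seed)
    baseline = np.asarray(config.baseline_monthly, dtype=float)
    gcm_ids = [f"GCM{i:02d}" for i in range(1, config.n_gcms + 1)]
    rows = []

    def emit(scenario, gcm, years, offset):
        for year in years:
            noise = rng.normal(0.0, config.interannual_sd, 12)
            tas = baseline + offset + noise
            for m in range(12):
                rows.append(
                    {
                        "region": config.region,
                        "scenario": scenario,
                        "gcm": gcm,
                        "year": int(year),
                        "month": m + 1,
                        "tas_C": float(tas[m]),
                    }
                )

    for gcm in gcm_ids:
        emit("historical", gcm, config.current.years, 0.0)
        for scenario, offset in config.warming_offsets.items():
            gcm_shift = rng.normal(0.0, config.inter_gcm_sd)
            emit(scenario, gcm, config.future.years, offset + gcm_shift)
    return pd.DataFrame(rows, columns=ENSEMBLE_COLUMNS)
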