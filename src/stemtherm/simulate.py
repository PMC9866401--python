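"""Individual-based simulation of egg→imago development at constant temperature.

A species model holds one thermal performance curve per immature life stage
(egg, larva, pupa). For an individual *i* and stage *j*, the development
rate ``r_ij(T)`` is drawn from a normal distribution centred on the stage
curve's rate ``τ_j(T)`` with standard deviation ``cv · τ_j(T)``, truncated
to non-negative values. Stage times are the inverses of the drawn rates and
the total immature development time is their sum; a zero stage rate makes
the total infinite. An individual "fails" when its total time exceeds the
host-plant growing season (182 days by default).

The thermal window ``(T50min, T50max)`` brackets the temperatures at which
at least half of a cohort completes development within the deadline. The
deterministic companion quantities are the total-rate curve
``r(T) = 1 / Σ_j 1/τ_j(T)`` and its maximum ``rmax``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError, DegenerateCurveError, EmptyWindowError
from .models import TPCParameterSet, evaluate_rate

__all__ = [
    "STAGES",
    "SpeciesDevelopmentModel",
    "SimulationSettings",
    "DevTimeDistribution",
    "ThermalWindow",
    "draw_individual_rates",
    "simulate_dev_times",
    "total_rate_curve",
    "rmax",
    "thermal_window",
]

STAGES = ("egg", "larva", "pupa")

#: default inter-individual coefficient of variation of development rates
DEFAULT_CV = 0.15


@dataclass(frozen=True)
class SpeciesDevelopmentModel:
    """Three stage curves (egg, larva, pupa) plus the rate coefficient of variation."""

    species: str
    stage_curves: Mapping[str, TPCParameterSet]
    cv: float = DEFAULT_CV

    def __post_init__(self):
        if set(self.stage_curves) != set(STAGES):
            raise ConfigurationError(
                f"stage_curves must have exactly the stages {STAGES}, "
                f"got {sorted(self.stage_curves)}"
            )
        if self.cv < 0:
            raise ConfigurationError("cv must be non-negative")

    def stage_rates(self, T) -> np.ndarray:
        """Mean stage rates τ_j(T) in stage order, shape (..., 3)."""
        return np.stack(
            [np.asarray(evaluate_rate(self.stage_curves[s], T)) for s in STAGES],
            axis=-1,
        )

    def with_cv(self, cv: float) -> "SpeciesDevelopmentModel":
        return replace(self, cv=cv)


@dataclass(frozen=True)
class SimulationSettings:
    """Cohort size, season deadline and RNG seed for the simulation."""

    n_individuals: int = 5000
    deadline_days: float = 182.0
    seed: int = 0
    grid_step: float = 0.5  # coarse scan step for the thermal window, °C

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if self.deadline_days <= 0:
            raise ConfigurationError("deadline_days must be positive")


@dataclass(frozen=True)
class DevTimeDistribution:
    """Simulated total development times of one cohort at one temperature."""

    temperature: float
    times: np.ndarray = field(repr=False)  # days; +inf for non-developers
    mean: float
    q2_5: float
    q97_5: float
    failure_fraction: float


@dataclass(frozen=True)
class ThermalWindow:
    """Temperatures bounding ≥50% cohort completion within the deadline."""

    t50min: float
    t50max: float
    deadline_days: float


def _temperature_rng(seed: int, T: float) -> np.random.Generator:
    # derive an independent stream per temperature so refining a scan grid
    # never reshuffles draws at previously visited temperatures
    return np.random.default_rng([int(seed), int(round(T * 1000))])


def _truncated_normal(rng, mu, sigma, size):
    """Draws from N(mu, sigma) truncated to [0, inf).

    Rejection sampling with an inverse-CDF fallback; at cv = 0.15 the
    truncated mass is ~1e-11 so rejection almost always succeeds at once.
    """
    x = rng.normal(mu, sigma, size)
    for _ in range(50):
        bad = x < 0
        if not bad.any():
            return x
        x[bad] = rng.normal(mu, sigma, int(bad.sum()))
    bad = x < 0
    if bad.any():  # pathological cv: invert the truncated CDF directly
        lo = norm.cdf(0.0, mu, sigma)
        u = rng.uniform(lo, 1.0, int(bad.sum()))
        x[bad] = norm.ppf(u, mu, sigma)
    return x


def draw_individual_rates(
    model: SpeciesDevelopmentModel,
    T: float,
    settings: SimulationSettings,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Individual stage rates, shape (n_individuals, 3).

    Independent truncated-normal draws per individual × stage; stages with a
    null mean rate yield exactly zero (no development at this temperature).
    """
    if rng is None:
        rng = _temperature_rng(settings.seed, T)
    tau = model.stage_rates(float(T))  # (3,)
    n = settings.n_individuals
    rates = np.zeros((n, 3))
    for j, t in enumerate(tau):
        if t <= 0.0:
            continue
        if model.cv == 0.0:
            rates[:, j] = t
        else:
            rates[:, j] = _truncated_normal(rng, t, model.cv * t, n)
    return rates


def simulate_dev_times(
    model: SpeciesDevelopmentModel,
    T: float,
    settings: SimulationSettings,
    rng: np.random.Generator | None = None,
) -> DevTimeDistribution:
    """Total egg→imago development times of a simulated cohort at ``T`` °C.

    ``d_i = Σ_j 1/r_ij``; any zero stage rate makes ``d_i`` infinite.
    Infinite times are kept: they count toward the failure fraction and are
    reflected in the summary statistics rather than dropped.
    """
    rates = draw_individual_rates(model, T, settings, rng)
    with np.errstate(divide="ignore"):
        stage_times = np.where(rates > 0.0, 1.0 / rates, np.inf)
    total = stage_times.sum(axis=1)
    # order-statistic quantiles: robust to infinite times (no interpolation)
    q_lo, q_hi = np.quantile(total, [0.025, 0.975], method="inverted_cdf")
    return DevTimeDistribution(
        temperature=float(T),
        times=total,
        mean=float(np.mean(total)),
        q2_5=float(q_lo),
        q97_5=float(q_hi),
        failure_fraction=float(np.mean(total > settings.deadline_days)),
    )


def total_rate_curve(model: SpeciesDevelopmentModel, grid) -> np.ndarray:
    """Deterministic whole-development rate ``r(T) = 1/Σ_j 1/τ_j(T)``.

    Zero wherever any stage has a null mean rate (the harmonic sum
    diverges: development cannot complete).
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    tau = model.stage_rates(grid)  # (n, 3)
    ok = np.all(tau > 0.0, axis=-1)
    out = np.zeros(len(grid))
    if ok.any():
        with np.errstate(divide="ignore"):
            out[ok] = 1.0 / (1.0 / tau[ok]).sum(axis=-1)
    return out


def rmax(
    model: SpeciesDevelopmentModel,
    t_min: float = 0.0,
    t_max: float = 50.0,
    step: float = 0.01,
) -> tuple[float, float]:
    """Maximum of the total-rate curve and its temperature, by grid search."""
    grid = np.arange(t_min, t_max + step, step)
    rates = total_rate_curve(model, grid)
    i = int(np.argmax(rates))
    if rates[i] <= 0.0:
        raise DegenerateCurveError(
            f"total-rate curve of {model.species} is zero on [{t_min}, {t_max}]"
        )
    return float(rates[i]), float(grid[i])


def _failure_at(model, T, settings) -> float:
    return simulate_dev_times(model, T, settings).failure_fraction


def thermal_window(
    model: SpeciesDevelopmentModel,
    settings: SimulationSettings,
    t_min: float = 0.0,
    t_max: float = 50.0,
    tol: float = 0.05,
) -> ThermalWindow:
    """Locate (T50min, T50max): the temperature range of ≥50% cohort success.

    A coarse scan at ``settings.grid_step`` °C finds temperatures where at
    most half the cohort fails; each boundary is then refined by bisection
    to ``tol`` °C. Every evaluation at a temperature uses its own
    deterministically derived RNG stream, so the scan and the bisection see
    consistent cohorts.
    """
    grid = np.arange(t_min, t_max + settings.grid_step, settings.grid_step)
    success = np.array([_failure_at(model, t, settings) <= 0.5 for t in grid])
    if not success.any():
        raise EmptyWindowError(
            f"no temperature in [{t_min}, {t_max}] allows 50% of the cohort "
            f"to develop within {settings.deadline_days} days"
        )
    idx = np.flatnonzero(success)
    first, last = idx[0], idx[-1]

    def bisect(lo, hi, want_low_side):
        # invariant: one end succeeds, the other fails
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            ok = _failure_at(model, mid, settings) <= 0.5
            if want_low_side:
                lo, hi = (lo, mid) if ok else (mid, hi)
            else:
                lo, hi = (mid, hi) if ok else (lo, mid)
        return 0.5 * (lo + hi)

    if first == 0:
        t50min = float(grid[0])
    else:
        t50min = bisect(grid[first - 1], grid[first], want_low_side=True)
    if last == len(grid) - 1:
        t50max = float(grid[-1])
    else:
        t50max = bisect(grid[last], grid[last + 1], want_low_side=False)
    return ThermalWindow(
        t50min=float(t50min), t50max=float(t50max), deadline_days=settings.deadline_days
    )
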