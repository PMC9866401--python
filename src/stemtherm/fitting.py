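"""Nonlinear least-squares fitting of stage curves and model selection.

Mean development times at constant temperatures (pooled across source
studies) are inverted to rates and each candidate model is fitted by
Levenberg–Marquardt least squares from multiple data-driven starting
points. Candidate fits are then ranked by AIC and filtered: fits far from
the best (ΔAIC ≥ 10) are discarded, fits within ΔAIC ≤ 2 are flagged as
statistically equivalent, and fits with biologically implausible thermal
limits (CTmin below 0 °C or CTmax above 50 °C) are discarded regardless of
their AIC. The lowest-AIC survivor is selected.

The AIC convention is the Gaussian least-squares one,
``AIC = n·ln(RSS/n) + 2(k+1)`` with ``k`` free curve parameters plus one
for the error variance; only AIC differences are ever interpreted, and
those are invariant to the additive constant this convention drops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .errors import InsufficientDataError, SelectionFailureError
from .models import (
    ThermalTraits,
    TPCModelSpec,
    TPCParameterSet,
    thermal_traits,
)

__all__ = [
    "RateObservation",
    "StageFit",
    "SelectionRules",
    "StudyEffectResult",
    "fit_stage",
    "akaike",
    "aic_from_rss",
    "select_model",
    "residual_diagnostics",
    "study_effect_check",
    "read_observations",
    "write_observations",
    "fit_report",
]


@dataclass(frozen=True)
class RateObservation:
    """One mean development time at one constant temperature.

    ``rate`` is the derived development rate 1/mean_dev_time (day⁻¹).
    """

    species: str
    stage: str
    study_id: str
    temperature: float  # °C
    mean_dev_time: float  # days

    def __post_init__(self):
        if not 0.0 <= self.temperature <= 50.0:
            raise ValueError(f"temperature {self.temperature} outside [0, 50] °C")
        if self.mean_dev_time <= 0:
            raise ValueError("mean_dev_time must be positive")

    @property
    def rate(self) -> float:
        return 1.0 / self.mean_dev_time


@dataclass
class StageFit:
    """One model fitted to the pooled observations of one life stage."""

    params: TPCParameterSet | None
    stderrs: dict[str, float]
    rss: float
    n_obs: int
    aic: float
    traits: ThermalTraits | None = None
    delta_aic: float | None = None
    status: str = "unselected"
    converged: bool = True
    perfect_fit: bool = False
    message: str = ""
    residuals: np.ndarray | None = field(default=None, repr=False)
    fitted: np.ndarray | None = field(default=None, repr=False)
    temperatures: np.ndarray | None = field(default=None, repr=False)

    @property
    def model_name(self) -> str:
        return self.params.model.name if self.params is not None else "?"

    @property
    def n_params(self) -> int:
        return len(self.params.model.parameter_names) if self.params is not None else 0


@dataclass(frozen=True)
class SelectionRules:
    """Thresholds of the selection ledger."""

    delta_aic_discard: float = 10.0
    delta_aic_equivalent: float = 2.0
    ctmin_floor: float = 0.0  # °C
    ctmax_ceiling: float = 50.0  # °C

    def __post_init__(self):
        if self.delta_aic_discard <= self.delta_aic_equivalent:
            raise ValueError("discard threshold must exceed the equivalence threshold")


def aic_from_rss(n: int, rss: float, k: int) -> float:
    """Gaussian least-squares AIC; −inf for an exactly zero RSS."""
    if rss <= 0.0:
        return -math.inf
    return n * math.log(rss / n) + 2.0 * (k + 1)


def akaike(fit: StageFit) -> float:
    """AIC of a fit (recomputed from its RSS, n and parameter count)."""
    return aic_from_rss(fit.n_obs, fit.rss, fit.n_params)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _eval_clamped(spec: TPCModelSpec, x: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Clamped curve evaluation from a raw parameter vector (no validation)."""
    values = dict(zip(spec.parameter_names, x))
    tl, th = values["CTmin"], values["CTmax"]
    out = np.zeros_like(T)
    if not (np.isfinite(x).all() and tl < th):
        return out
    inside = (T > tl) & (T < th)
    if inside.any():
        with np.errstate(all="ignore"):
            raw = spec.raw(T[inside], values)
        out[inside] = np.maximum(np.nan_to_num(raw, nan=0.0, posinf=0.0, neginf=0.0), 0.0)
    return out


# shape-parameter starting values per model (thresholds and scale are data-driven)
_SHAPE_STARTS: dict[str, dict[str, float]] = {
    "analytis_77": {"b": 2.0, "c": 1.0},
    "ratkowsky_83": {"k": 0.2},
    "hilbertLogan_83": {"a": 5.0, "deltaT": 5.0},
    "beta_95": {"a": 2.0, "b": 1.0},
    "beta_16": {},
    "briere1_99": {},
    "briere2_99": {"b": 2.0},
    "kontodimas_04": {},
    "shi_11": {"k1": 0.2, "k2": 0.3},
    "perf2_11": {"k": 0.3},
    "regniere_12": {"b": 0.1, "deltab": 5.0, "deltam": 5.0},
}


def _initial_values(spec: TPCModelSpec, T: np.ndarray, r: np.ndarray) -> dict[str, float]:
    """Data-driven starting point: thresholds straddle the observed range,
    the scale parameter matches the largest observed rate."""
    tl0 = float(T.min()) - 2.0
    th0 = float(T.max()) + 2.0
    r_peak = float(r.max())
    t_peak = float(T[np.argmax(r)])
    x0 = dict(_SHAPE_STARTS[spec.name])
    x0["CTmin"] = tl0
    x0["CTmax"] = th0
    if spec.name == "beta_16":
        x0["Topt"] = t_peak
        x0["rm"] = r_peak
    elif spec.name == "ratkowsky_83":
        denom = (t_peak - tl0) * (1.0 - math.exp(x0["k"] * (t_peak - th0)))
        x0["c"] = math.sqrt(r_peak) / denom if denom > 0 else 0.01
    elif spec.name == "beta_95":
        x0["mu"] = (
            math.log(r_peak)
            - x0["a"] * math.log(t_peak - tl0)
            - x0["b"] * math.log(th0 - t_peak)
        )
    elif spec.scale_param is not None:
        probe = dict(x0)
        probe[spec.scale_param] = 1.0
        xv = np.array([probe[p] for p in spec.parameter_names])
        unit = _eval_clamped(spec, xv, np.asarray([t_peak], dtype=float))[0]
        x0[spec.scale_param] = r_peak / unit if unit > 0 else r_peak
    return x0


def _jittered(x0: dict[str, float], spec: TPCModelSpec, rng) -> dict[str, float]:
    x = {}
    for name, v in x0.items():
        if name in ("CTmin", "CTmax"):
            x[name] = v + rng.normal(0.0, 1.0)
        else:
            x[name] = v * (1.0 + 0.1 * rng.normal())
    if x["CTmin"] >= x["CTmax"]:
        x["CTmin"], x["CTmax"] = x0["CTmin"], x0["CTmax"]
    return x


def fit_stage(
    observations: Sequence[RateObservation],
    model: TPCModelSpec,
    seed: int = 0,
    n_starts: int = 20,
) -> StageFit:
    """Fit one model to pooled rate observations by Levenberg–Marquardt NLS.

    Multiple jittered restarts around a data-driven starting point are run
    and the best residual sum of squares is kept. Standard errors come from
    the Gauss–Newton curvature at the optimum, ``(JᵀJ)⁻¹ · RSS/(n−k)``.
    Raises :class:`InsufficientDataError` when there are no more
    observations than free parameters; returns a non-converged fit record
    (never raises) when every restart fails.
    """
    obs = list(observations)
    k = len(model.parameter_names)
    n = len(obs)
    if n <= k:
        raise InsufficientDataError(
            f"{n} observations cannot constrain the {k}-parameter model {model.name}"
        )
    T = np.array([o.temperature for o in obs], dtype=float)
    r = np.array([o.rate for o in obs], dtype=float)
    names = model.parameter_names

    def residual(x):
        return _eval_clamped(model, x, T) - r

    rng = np.random.default_rng(seed)
    x0_base = _initial_values(model, T, r)
    best = None
    for start in range(n_starts):
        x0 = x0_base if start == 0 else _jittered(x0_base, model, rng)
        xv = np.array([x0[p] for p in names], dtype=float)
        try:
            res = least_squares(residual, xv, method="lm", max_nfev=2000 * k)
        except Exception:
            continue
        if not np.isfinite(res.x).all():
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res)

    if best is None:
        return StageFit(
            params=None, stderrs={}, rss=math.inf, n_obs=n, aic=math.inf,
            converged=False, status="failed", message="no restart converged",
        )

    rss, res = best
    values = dict(zip(names, (float(v) for v in res.x)))
    # validity of the solution itself
    valid = values["CTmin"] < values["CTmax"]
    if model.name == "beta_16":
        valid = valid and values["CTmin"] < values["Topt"] < values["CTmax"]
    if not valid:
        return StageFit(
            params=None, stderrs={}, rss=rss, n_obs=n, aic=math.inf,
            converged=False, status="failed",
            message="optimum violates threshold ordering",
        )

    params = TPCParameterSet(model=model, values=values)
    fitted = _eval_clamped(model, res.x, T)
    resid = r - fitted

    dof = n - k
    stderrs = {p: math.nan for p in names}
    if dof > 0 and rss > 0:
        J = res.jac
        try:
            cov = np.linalg.inv(J.T @ J) * rss / dof
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            stderrs = dict(zip(names, (float(s) for s in se)))
        except np.linalg.LinAlgError:
            pass

    try:
        traits = thermal_traits(params)
    except Exception:
        traits = None

    aic = aic_from_rss(n, rss, k)
    return StageFit(
        params=params,
        stderrs=stderrs,
        rss=rss,
        n_obs=n,
        aic=aic,
        traits=traits,
        perfect_fit=not math.isfinite(aic),
        residuals=resid,
        fitted=fitted,
        temperatures=T,
    )


# ---------------------------------------------------------------------------
# selection ledger
# ---------------------------------------------------------------------------

def select_model(
    fits: Sequence[StageFit], rules: SelectionRules = SelectionRules()
) -> StageFit:
    """Apply the selection ledger and return the winning fit.

    Pipeline: (1) ΔAIC against the best fit, discard ΔAIC ≥ 10;
    (2) flag ΔAIC ≤ 2 as statistically equivalent; (3) discard fits with
    CTmin below 0 °C or CTmax above 50 °C; (4) the lowest-AIC survivor is
    selected. All fits are annotated in place with ``delta_aic``/``status``.
    Raises :class:`SelectionFailureError` (with per-fit reasons) when
    nothing survives.
    """
    converged = [f for f in fits if f.converged and f.params is not None]
    if not converged:
        raise SelectionFailureError(
            "no converged fit to select from",
            reasons={f.model_name: f.message or "did not converge" for f in fits},
        )
    best_aic = min(f.aic for f in converged)
    reasons: dict[str, str] = {}
    survivors = []
    for f in converged:
        f.delta_aic = 0.0 if f.aic == best_aic else f.aic - best_aic
        if f.delta_aic >= rules.delta_aic_discard:
            f.status = "discarded_aic"
            reasons[f.model_name] = f"ΔAIC={f.delta_aic:.1f} ≥ {rules.delta_aic_discard}"
            continue
        tl, th = f.params.ctmin, f.params.ctmax
        if tl < rules.ctmin_floor or th > rules.ctmax_ceiling:
            f.status = "discarded_biology"
            reasons[f.model_name] = (
                f"CTmin={tl:.1f}, CTmax={th:.1f} outside "
                f"[{rules.ctmin_floor}, {rules.ctmax_ceiling}] °C"
            )
            continue
        survivors.append(f)
    if not survivors:
        for f in fits:
            if not f.converged:
                reasons.setdefault(f.model_name, f.message or "did not converge")
        raise SelectionFailureError("no fit survives the selection filters", reasons)
    winner = min(survivors, key=lambda f: f.aic)
    for f in survivors:
        f.status = "equivalent" if f.delta_aic <= rules.delta_aic_equivalent else "candidate"
    winner.status = "selected"
    return winner


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def residual_diagnostics(fit: StageFit) -> dict:
    """Residual table plus a normality statistic and a scale-location slope.

    Nothing is rejected automatically; this mirrors graphical residual
    checking (homoscedasticity and normality) and exports the raw material
    for plots.
    """
    if fit.residuals is None:
        raise ValueError("fit carries no residuals (non-converged?)")
    resid = fit.residuals
    table = pd.DataFrame(
        {
            "temperature_C": fit.temperatures,
            "fitted_rate": fit.fitted,
            "residual": resid,
        }
    )
    scale = resid.std(ddof=1) if len(resid) > 1 else 0.0
    std_resid = resid / scale if scale > 0 else resid * 0.0
    table["std_residual"] = std_resid
    if len(resid) >= 3 and scale > 0:
        shapiro_stat, shapiro_p = stats.shapiro(resid)
        slope = float(
            np.polyfit(fit.fitted, np.sqrt(np.abs(std_resid)), 1)[0]
        )
    else:
        shapiro_stat, shapiro_p, slope = math.nan, math.nan, math.nan
    return {
        "table": table,
        "shapiro_stat": float(shapiro_stat),
        "shapiro_p": float(shapiro_p),
        "scale_location_slope": slope,
    }


@dataclass(frozen=True)
class StudyEffectResult:
    """One-way ANOVA of fit residuals grouped by source study."""

    applicable: bool
    n_studies: int
    f_statistic: float = math.nan
    p_value: float = math.nan


def study_effect_check(
    fit: StageFit, observations: Sequence[RateObservation]
) -> StudyEffectResult:
    """Test for a residual study effect after pooled fitting.

    Operationalized as a one-way ANOVA of the fit residuals grouped by
    ``study_id`` (the pooled NLS cannot carry a random study factor, so the
    check is post hoc on residuals). Not applicable with fewer than two
    studies.
    """
    if fit.residuals is None or len(observations) != len(fit.residuals):
        raise ValueError("observations must be those the fit was computed from")
    groups: dict[str, list[float]] = {}
    for o, res in zip(observations, fit.residuals):
        groups.setdefault(o.study_id, []).append(float(res))
    if len(groups) < 2:
        return StudyEffectResult(applicable=False, n_studies=len(groups))
    f_stat, p = stats.f_oneway(*groups.values())
    return StudyEffectResult(
        applicable=True, n_studies=len(groups), f_statistic=float(f_stat), p_value=float(p)
    )


# ---------------------------------------------------------------------------
# file dialects
# ---------------------------------------------------------------------------

_OBS_COLUMNS = ["species", "stage", "study_id", "temperature_C", "mean_dev_time_days"]


def read_observations(path) -> list[RateObservation]:
    """Read an observation table (CSV with the documented header)."""
    df = pd.read_csv(path)
    missing = set(_OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation file {path} lacks columns {sorted(missing)}")
    return [
        RateObservation(
            species=row.species,
            stage=row.stage,
            study_id=str(row.study_id),
            temperature=float(row.temperature_C),
            mean_dev_time=float(row.mean_dev_time_days),
        )
        for row in df.itertuples()
    ]


def write_observations(observations: Iterable[RateObservation], path) -> None:
    pd.DataFrame(
        [
            {
                "species": o.species,
                "stage": o.stage,
                "study_id": o.study_id,
                "temperature_C": o.temperature,
                "mean_dev_time_days": o.mean_dev_time,
            }
            for o in observations
        ],
        columns=_OBS_COLUMNS,
    ).to_csv(path, index=False)


def fit_report(fits: Sequence[StageFit]) -> pd.DataFrame:
    """Long-format report: one row per fitted parameter, plus fit statistics."""
    rows = []
    for f in fits:
        if f.params is None:
            rows.append(
                {"model": f.model_name, "parameter": None, "estimate": math.nan,
                 "stderr": math.nan, "rss": f.rss, "n": f.n_obs, "aic": f.aic,
                 "delta_aic": f.delta_aic, "status": f.status}
            )
            continue
        for p in f.params.model.parameter_names:
            rows.append(
                {
                    "model": f.model_name,
                    "parameter": p,
                    "estimate": f.params.values[p],
                    "stderr": f.stderrs.get(p, math.nan),
                    "rss": f.rss,
                    "n": f.n_obs,
                    "aic": f.aic,
                    "delta_aic": f.delta_aic,
                    "status": f.status,
                }
            )
    return pd.DataFrame(rows)
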