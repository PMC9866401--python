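"""Climate-warming impact on development, via the r/rmax metric.

Monthly near-surface temperatures from an ensemble of global circulation
models (GCMs) — regional aggregates in the style of the IPCC WGI
Interactive Atlas — are averaged per calendar month over a current period
(1990–2014) and a future period (2081–2100, under SSP1-2.6 or SSP5-8.5).
For each month and GCM, the deterministic whole-development rate at the
monthly mean temperature is divided by the species' maximum rate ``rmax``,
giving the fraction of maximal development ``r/rmax`` in [0, 1] (zero when
any stage cannot develop). The per-month difference future − current lies
in [−1, 1] and quantifies the benefit (+) or harm (−) of warming to
development.

Ensembles are consumed as flat tables with columns
``region, scenario, gcm, year, month, tas_C`` — the adapter target for
Atlas regional exports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingDataError
from .simulate import SpeciesDevelopmentModel, rmax, total_rate_curve

__all__ = [
    "PeriodSpec",
    "CURRENT_PERIOD",
    "FUTURE_PERIOD",
    "SCENARIOS",
    "normalize_scenario",
    "read_ensemble",
    "write_ensemble",
    "period_monthly_means",
    "r_over_rmax",
    "impact_difference",
    "compute_impacts",
    "ensemble_summary",
]

ENSEMBLE_COLUMNS = ["region", "scenario", "gcm", "year", "month", "tas_C"]

SCENARIOS = ("historical", "ssp126", "ssp585")

_SCENARIO_ALIASES = {
    "historical": "historical",
    "hist": "historical",
    "ssp126": "ssp126",
    "ssp1-2.6": "ssp126",
    "ssp1_2_6": "ssp126",
    "ssp585": "ssp585",
    "ssp5-8.5": "ssp585",
    "ssp5_8_5": "ssp585",
}


@dataclass(frozen=True)
class PeriodSpec:
    """An inclusive year range over which monthly climatologies are taken."""

    label: str
    year_start: int
    year_end: int

    def __post_init__(self):
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)


CURRENT_PERIOD = PeriodSpec("current", 1990, 2014)
FUTURE_PERIOD = PeriodSpec("future", 2081, 2100)


def normalize_scenario(label: str) -> str:
    key = str(label).strip().lower()
    try:
        return _SCENARIO_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown scenario {label!r}; recognized: {sorted(set(_SCENARIO_ALIASES))}"
        ) from None


def read_ensemble(path) -> pd.DataFrame:
    """Read a monthly-temperature ensemble table, normalizing scenario labels."""
    df = pd.read_csv(path)
    missing = set(ENSEMBLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ensemble file {path} lacks columns {sorted(missing)}")
    df = df.copy()
    df["scenario"] = df["scenario"].map(normalize_scenario)
    bad_month = ~df["month"].between(1, 12)
    if bad_month.any():
        raise ValueError(f"{int(bad_month.sum())} rows with month outside 1..12")
    return df


def write_ensemble(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=ENSEMBLE_COLUMNS)


def period_monthly_means(records: pd.DataFrame, period: PeriodSpec) -> np.ndarray:
    """Mean temperature per calendar month over a period, for one GCM series.

    Every year-month of the period must be present exactly once; gaps raise
    :class:`MissingDataError` naming the missing (year, month) pairs.
    Calendar months are weighted equally.
    """
    sub = records[records["year"].between(period.year_start, period.year_end)]
    have = set(zip(sub["year"].astype(int), sub["month"].astype(int)))
    expect = {(y, m) for y in period.years for m in range(1, 13)}
    gaps = sorted(expect - have)
    if gaps:
        shown = ", ".join(f"{y}-{m:02d}" for y, m in gaps[:12])
        more = f" (+{len(gaps) - 12} more)" if len(gaps) > 12 else ""
        raise MissingDataError(
            f"period {period.label} ({period.year_start}–{period.year_end}) "
            f"is missing year-months: {shown}{more}"
        )
    if len(sub) != len(expect):
        raise MissingDataError(
            f"duplicate year-month rows in period {period.label}"
        )
    means = sub.groupby("month")["tas_C"].mean()
    return means.reindex(range(1, 13)).to_numpy()


def r_over_rmax(
    model: SpeciesDevelopmentModel, T, rmax_value: float | None = None
) -> np.ndarray | float:
    """Fraction of maximal development reached at temperature(s) ``T``.

    1 at the temperature maximizing the total-rate curve; exactly 0 when
    any stage's rate is null.
    """
    if rmax_value is None:
        rmax_value, _ = rmax(model)
    vals = total_rate_curve(model, T) / rmax_value
    vals = np.clip(vals, 0.0, 1.0)
    if np.isscalar(T) or np.ndim(T) == 0:
        return float(vals[0])
    return vals


def impact_difference(
    model: SpeciesDevelopmentModel,
    current_means,
    future_means,
    rmax_value: float | None = None,
) -> np.ndarray:
    """Per-month ``r/rmax(future) − r/rmax(current)``, each in [−1, 1]."""
    cur = np.asarray(current_means, dtype=float)
    fut = np.asarray(future_means, dtype=float)
    if cur.shape != (12,) or fut.shape != (12,):
        raise ValueError("current_means and future_means must each hold 12 values")
    if rmax_value is None:
        rmax_value, _ = rmax(model)
    return r_over_rmax(model, fut, rmax_value) - r_over_rmax(model, cur, rmax_value)


def compute_impacts(
    model: SpeciesDevelopmentModel,
    ensemble: pd.DataFrame,
    region: str,
    scenario: str,
    current: PeriodSpec = CURRENT_PERIOD,
    future: PeriodSpec = FUTURE_PERIOD,
) -> pd.DataFrame:
    """Per-GCM, per-month impact records for one region and future scenario.

    Current conditions come from each GCM's historical series; the future
    from its series under ``scenario``. GCMs present in only one of the two
    are skipped (ensemble sizes differ between scenarios). Columns:
    species, region, scenario, gcm, month, r_over_rmax_current,
    r_over_rmax_future, difference.
    """
    scenario = normalize_scenario(scenario)
    reg = ensemble[ensemble["region"] == region]
    hist = reg[reg["scenario"] == "historical"]
    fut = reg[reg["scenario"] == scenario]
    gcms = sorted(set(hist["gcm"]) & set(fut["gcm"]))
    if not gcms:
        raise ValueError(
            f"no GCM has both historical and {scenario} records for region {region!r}"
        )
    rmax_value, _ = rmax(model)
    rows = []
    for gcm in gcms:
        cur_means = period_monthly_means(hist[hist["gcm"] == gcm], current)
        fut_means = period_monthly_means(fut[fut["gcm"] == gcm], future)
        cur_frac = r_over_rmax(model, cur_means, rmax_value)
        fut_frac = r_over_rmax(model, fut_means, rmax_value)
        for m in range(12):
            rows.append(
                {
                    "species": model.species,
                    "region": region,
                    "scenario": scenario,
                    "gcm": gcm,
                    "month": m + 1,
                    "r_over_rmax_current": cur_frac[m],
                    "r_over_rmax_future": fut_frac[m],
                    "difference": fut_frac[m] - cur_frac[m],
                }
            )
    return pd.DataFrame(rows)


def ensemble_summary(impacts: pd.DataFrame) -> pd.DataFrame:
    """Across-GCM summary of the monthly r/rmax differences.

    One row per (species, region, scenario, month) with the mean, extrema
    and quartiles (linear interpolation between order statistics) and the
    number of GCMs.
    """
    grouped = impacts.groupby(["species", "region", "scenario", "month"])["difference"]
    out = grouped.agg(
        mean="mean",
        min="min",
        q25=lambda s: s.quantile(0.25),
        median="median",
        q75=lambda s: s.quantile(0.75),
        max="max",
        n_gcms="count",
    ).reset_index()
    return out
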