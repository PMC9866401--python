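"""Catalog of nonlinear development-rate models (thermal performance curves).

Each model maps a constant rearing temperature ``T`` (°C) to a development
rate (day⁻¹, the fraction of a life stage completed per day). All models
share two biologically interpretable thresholds: the critical thermal
minimum ``CTmin`` and maximum ``CTmax``, outside of which development is
null. Every curve is evaluated under a uniform non-negativity contract:
raw formula values are clamped to zero, and the rate is exactly zero for
``T ≤ CTmin`` or ``T ≥ CTmax``. The optimal temperature ``Topt`` is the
local maximum of the curve on ``[CTmin, CTmax]``.

The eleven model forms are the classical ones from the insect-development
literature (Analytis, Ratkowsky, Hilbert & Logan, two beta forms, the two
Brière curves, Kontodimas, the Shi/performance pair, and Régnière's
thermodynamic approximation), restricted to those that expose CTmin and
CTmax as parameters so thermal limits can be estimated directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ConfigurationError, DegenerateCurveError

__all__ = [
    "TPCModelSpec",
    "TPCParameterSet",
    "ThermalTraits",
    "MODEL_NAMES",
    "get_model",
    "list_models",
    "evaluate_rate",
    "thermal_traits",
    "topt_closed_form",
]


@dataclass(frozen=True)
class TPCModelSpec:
    """Description of one development-rate model.

    Parameters
    ----------
    name : str
        Registry key (e.g. ``"briere1_99"``).
    parameter_names : tuple of str
        Ordered free-parameter symbols; always includes ``CTmin`` and
        ``CTmax``.
    has_closed_form_topt : bool
        Whether the stationary point of the curve has an analytical
        expression (used as an independent cross-check of the numeric
        optimum).
    scale_param : str or None
        Symbol that scales the whole curve linearly, if one exists
        (``None`` for forms where no single parameter acts linearly).
    """

    name: str
    parameter_names: tuple[str, ...]
    has_closed_form_topt: bool = False
    scale_param: str | None = None
    _raw: Callable[..., np.ndarray] = field(default=None, repr=False, compare=False)

    def raw(self, T: np.ndarray, values: Mapping[str, float]) -> np.ndarray:
        """Unclamped formula value (may be negative or NaN outside the domain)."""
        args = [values[p] for p in self.parameter_names]
        return self._raw(np.asarray(T, dtype=float), *args)


@dataclass(frozen=True)
class TPCParameterSet:
    """A model together with concrete parameter values.

    Temperatures are °C, rates day⁻¹. Validates symbol names against the
    model and the ordering ``CTmin < CTmax`` on construction.
    """

    model: TPCModelSpec
    values: Mapping[str, float]

    def __post_init__(self):
        unknown = set(self.values) - set(self.model.parameter_names)
        if unknown:
            raise ConfigurationError(
                f"unknown symbol(s) {sorted(unknown)} for model {self.model.name}; "
                f"expected {list(self.model.parameter_names)}"
            )
        missing = set(self.model.parameter_names) - set(self.values)
        if missing:
            raise ConfigurationError(
                f"missing symbol(s) {sorted(missing)} for model {self.model.name}"
            )
        for k, v in self.values.items():
            if not math.isfinite(v):
                raise ConfigurationError(f"non-finite value for {k} in {self.model.name}")
        if not self.values["CTmin"] < self.values["CTmax"]:
            raise ConfigurationError(
                f"CTmin ({self.values['CTmin']}) must be < CTmax ({self.values['CTmax']})"
            )

    @property
    def ctmin(self) -> float:
        return float(self.values["CTmin"])

    @property
    def ctmax(self) -> float:
        return float(self.values["CTmax"])


@dataclass(frozen=True)
class ThermalTraits:
    """Thermal limits and optimum of one curve (all °C); CTmin ≤ Topt ≤ CTmax."""

    CTmin: float
    CTmax: float
    Topt: float

    def __post_init__(self):
        if not (self.CTmin <= self.Topt <= self.CTmax):
            raise ConfigurationError("Topt must lie within [CTmin, CTmax]")


# ---------------------------------------------------------------------------
# Raw model formulas. Arguments follow each spec's parameter_names order.
# np.errstate is handled by the evaluator; invalid values become 0 there.
# ---------------------------------------------------------------------------

def _analytis_77(T, a, b, c, CTmin, CTmax):
    return a * (T - CTmin) ** b * (CTmax - T) ** c


def _ratkowsky_83(T, c, k, CTmin, CTmax):
    # square-root form: sqrt(r) is linear below the optimum
    return (c * (T - CTmin) * (1.0 - np.exp(k * (T - CTmax)))) ** 2


def _hilbert_logan_83(T, phi, a, deltaT, CTmin, CTmax):
    # Logan-type composite with a base-temperature shift; transcribed from
    # the original sigmoid-times-decay form:
    #   r = phi * [ u² / (u² + a²) − exp(−(CTmax − u) / ΔT) ],  u = T − CTmin
    u = T - CTmin
    return phi * (u**2 / (u**2 + a**2) - np.exp(-(CTmax - u) / deltaT))


def _beta_95(T, mu, a, b, CTmin, CTmax):
    return np.exp(mu) * (T - CTmin) ** a * (CTmax - T) ** b


def _beta_16(T, rm, Topt, CTmin, CTmax):
    expo = (Topt - CTmin) / (CTmax - Topt)
    return (
        rm
        * ((CTmax - T) / (CTmax - Topt))
        * ((T - CTmin) / (Topt - CTmin)) ** expo
    )


def _briere1_99(T, a, CTmin, CTmax):
    return a * T * (T - CTmin) * np.sqrt(CTmax - T)


def _briere2_99(T, a, b, CTmin, CTmax):
    return a * T * (T - CTmin) * (CTmax - T) ** (1.0 / b)


def _kontodimas_04(T, a, CTmin, CTmax):
    return a * (T - CTmin) ** 2 * (CTmax - T)


def _shi_11(T, c, k1, k2, CTmin, CTmax):
    return c * (1.0 - np.exp(-k1 * (T - CTmin))) * (1.0 - np.exp(k2 * (T - CTmax)))


def _perf2_11(T, c, k, CTmin, CTmax):
    return c * (T - CTmin) * (1.0 - np.exp(k * (T - CTmax)))


def _regniere_12(T, phi, b, deltab, deltam, CTmin, CTmax):
    # Thermodynamic approximation with exponential decay toward both
    # thresholds; transcribed from the original six-parameter form
    # (base temperature = CTmin, lethal maximum = CTmax):
    #   r = phi * [ e^{b(T−CTmin)}
    #               − (CTmax−T)/(CTmax−CTmin) · e^{−b(T−CTmin)/Δb}
    #               − (T−CTmin)/(CTmax−CTmin) · e^{b(CTmax−CTmin) − (CTmax−T)/Δm} ]
    u = T - CTmin
    span = CTmax - CTmin
    return phi * (
        np.exp(b * u)
        - ((CTmax - T) / span) * np.exp(-b * u / deltab)
        - (u / span) * np.exp(b * span - (CTmax - T) / deltam)
    )


_REGISTRY: dict[str, TPCModelSpec] = {}


def _register(name, parameter_names, raw, *, closed_form=False, scale=None):
    spec = TPCModelSpec(
        name=name,
        parameter_names=tuple(parameter_names),
        has_closed_form_topt=closed_form,
        scale_param=scale,
        _raw=raw,
    )
    _REGISTRY[name] = spec
    return spec


_register("analytis_77", ("a", "b", "c", "CTmin", "CTmax"), _analytis_77, scale="a")
_register("ratkowsky_83", ("c", "k", "CTmin", "CTmax"), _ratkowsky_83)
_register(
    "hilbertLogan_83",
    ("phi", "a", "deltaT", "CTmin", "CTmax"),
    _hilbert_logan_83,
    scale="phi",
)
_register("beta_95", ("mu", "a", "b", "CTmin", "CTmax"), _beta_95)
_register("beta_16", ("rm", "Topt", "CTmin", "CTmax"), _beta_16, scale="rm")
_register("briere1_99", ("a", "CTmin", "CTmax"), _briere1_99, closed_form=True, scale="a")
_register("briere2_99", ("a", "b", "CTmin", "CTmax"), _briere2_99, scale="a")
_register("kontodimas_04", ("a", "CTmin", "CTmax"), _kontodimas_04, closed_form=True, scale="a")
_register("shi_11", ("c", "k1", "k2", "CTmin", "CTmax"), _shi_11, scale="c")
_register("perf2_11", ("c", "k", "CTmin", "CTmax"), _perf2_11, scale="c")
_register("regniere_12", ("phi", "b", "deltab", "deltam", "CTmin", "CTmax"), _regniere_12, scale="phi")

MODEL_NAMES: tuple[str, ...] = tuple(_REGISTRY)


def list_models() -> Sequence[TPCModelSpec]:
    """Return the eleven model specifications, in registry order."""
    return list(_REGISTRY.values())


def get_model(name: str) -> TPCModelSpec:
    """Look up a model spec by name; raises ConfigurationError if unknown."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown model {name!r}; available: {', '.join(MODEL_NAMES)}"
        ) from None


def evaluate_rate(params: TPCParameterSet, T) -> np.ndarray | float:
    """Development rate (day⁻¹) at temperature(s) ``T`` (°C).

    The raw model formula is clamped to be non-negative, and the rate is
    exactly zero at and beyond the thermal thresholds (development is null
    below CTmin and above CTmax). Undefined expressions outside the domain
    (e.g. the square root of a negative number) also map to zero.
    """
    T_arr = np.atleast_1d(np.asarray(T, dtype=float))
    out = np.zeros_like(T_arr)
    inside = (T_arr > params.ctmin) & (T_arr < params.ctmax)
    if inside.any():
        with np.errstate(all="ignore"):
            raw = params.model.raw(T_arr[inside], params.values)
        raw = np.nan_to_num(raw, nan=0.0, posinf=0.0, neginf=0.0)
        out[inside] = np.maximum(raw, 0.0)
    if np.isscalar(T) or np.ndim(T) == 0:
        return float(out[0])
    return out


def topt_closed_form(params: TPCParameterSet) -> float:
    """Analytical optimum temperature for the models that have one.

    For the cubic-in-T Kontodimas form the stationary point is
    ``(2·CTmax + CTmin) / 3``. For the Brière-1 form the root of the
    rate derivative is
    ``(4·CTmax + 3·CTmin + sqrt(16·CTmax² + 9·CTmin² − 16·CTmin·CTmax)) / 10``.
    """
    tl, th = params.ctmin, params.ctmax
    if params.model.name == "kontodimas_04":
        return (2.0 * th + tl) / 3.0
    if params.model.name == "briere1_99":
        disc = 16.0 * th**2 + 9.0 * tl**2 - 16.0 * tl * th
        return (4.0 * th + 3.0 * tl + math.sqrt(disc)) / 10.0
    raise ConfigurationError(
        f"model {params.model.name} has no closed-form optimum"
    )


def thermal_traits(params: TPCParameterSet, *, grid_step: float = 0.01) -> ThermalTraits:
    """Locate the thermal optimum of a curve numerically.

    A grid scan at ``grid_step`` °C brackets the maximum (robust to mild
    multi-modality; ties resolve to the lower temperature), then a bounded
    scalar minimization refines it to better than 1e-4 °C.
    """
    tl, th = params.ctmin, params.ctmax
    grid = np.arange(tl, th + grid_step, grid_step)
    rates = evaluate_rate(params, grid)
    if not np.any(rates > 0):
        raise DegenerateCurveError(
            f"curve {params.model.name} is zero everywhere on [{tl}, {th}]"
        )
    i = int(np.argmax(rates))  # argmax returns the first (lowest-T) maximizer
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda t: -evaluate_rate(params, float(t)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-5},
    )
    topt = float(np.clip(res.x, tl, th))
    # the refined point must not be worse than the grid maximizer
    if evaluate_rate(params, topt) < rates[i]:
        topt = float(grid[i])
    return ThermalTraits(CTmin=tl, CTmax=th, Topt=topt)
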