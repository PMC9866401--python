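"""Independent oracles used by the test suite.

These deliberately avoid the package's simulation code paths: failure
probabilities come from numerical integration over the truncated-normal
stage-rate distributions, and deterministic window bounds from root
finding on the total-time curve.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.signal import fftconvolve
from scipy.stats import norm


def stage_time_cdf(t, tau, cv):
    """P(stage time ≤ t) for time = 1/rate, rate ~ N(tau, cv·tau) on [0, ∞)."""
    t = np.asarray(t, dtype=float)
    mu, sigma = tau, cv * tau
    trunc = 1.0 - norm.cdf(0.0, mu, sigma)  # mass kept by truncation at 0
    with np.errstate(divide="ignore"):
        r_min = np.where(t > 0, 1.0 / t, np.inf)
    return np.where(t > 0, (1.0 - norm.cdf(r_min, mu, sigma)) / trunc, 0.0)


def failure_probability_numeric(model, T, deadline=182.0, h=0.02):
    """P(total development time > deadline) by convolution of stage-time laws.

    Only mass below the deadline matters for the success probability, so
    each stage-time distribution is discretized on [0, deadline] with step
    ``h``; two stages are convolved and the third enters through its exact
    CDF. Any stage with a null mean rate forces certain failure.
    """
    tau = model.stage_rates(float(T))
    if np.any(tau <= 0.0):
        return 1.0
    cv = model.cv
    if cv == 0.0:
        return float((1.0 / tau).sum() > deadline)
    edges = np.arange(0.0, deadline + h, h)
    mids = 0.5 * (edges[:-1] + edges[1:])
    pmfs = [np.diff(stage_time_cdf(edges, t, cv)) for t in tau]
    g = fftconvolve(pmfs[0], pmfs[1])[: len(mids)]
    # sum s of stages 1+2 sits near midpoint 2*mids-ish; grid of g is mids[i]+mids[j]
    s = np.arange(len(g)) * h + 2 * mids[0]
    success = float(np.sum(g * stage_time_cdf(deadline - s, tau[2], cv)))
    return 1.0 - success


def deterministic_window(model, deadline=182.0, lo=0.0, hi=50.0):
    """Crossings of Σ_j 1/τ_j(T) = deadline, by bisection on a fine scan."""

    def total_time(T):
        tau = model.stage_rates(float(T))
        if np.any(tau <= 0.0):
            return np.inf
        return float((1.0 / tau).sum())

    grid = np.arange(lo, hi, 0.05)
    ok = np.array([total_time(t) <= deadline for t in grid])
    idx = np.flatnonzero(ok)
    assert idx.size, "development fails everywhere"
    f = lambda T: min(total_time(T), 1e9) - deadline
    t_lo = grid[idx[0]] if idx[0] == 0 else brentq(f, grid[idx[0] - 1], grid[idx[0]], xtol=1e-6)
    t_hi = (
        grid[idx[-1]]
        if idx[-1] == len(grid) - 1
        else brentq(f, grid[idx[-1]], grid[idx[-1] + 1], xtol=1e-6)
    )
    return float(t_lo), float(t_hi)
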