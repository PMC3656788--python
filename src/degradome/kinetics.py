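"""Sigmoidal degradation kinetics.

Cellulose degradation curves are fitted with a 3-parameter logistic
D(t) = K / (1 + exp(-r (t - t0))): K is the degradable asymptote (g/L),
r the steepness (1/day) and t0 the inflection day. The peak degradation rate
is the derivative at the inflection, r*K/4 (g/L/day), and the lag time (days
to reach the peak rate) is t0 itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


def logistic(t: np.ndarray, K: float, r: float, t0: float) -> np.ndarray:
    return K / (1.0 + np.exp(-r * (np.asarray(t, dtype=float) - t0)))


@dataclass
class SigmoidFit:
    K: float
    r: float
    t0: float
    peak_rate: float
    lag_time: float
    rss: float
    converged: bool


def _initial_guess(t: np.ndarray, d: np.ndarray) -> tuple[float, float, float]:
    K0 = float(d.max())
    half = K0 / 2.0
    above = np.nonzero(d >= half)[0]
    t0 = float(t[above[0]]) if above.size else float(np.median(t))
    slopes = np.diff(d) / np.diff(t)
    max_slope = float(slopes.max()) if slopes.size else 1.0
    r0 = max(4.0 * max_slope / K0, 1e-3) if K0 > 0 else 1.0
    return K0, r0, t0


def fit_sigmoid_extract(
    timepoints,
    degraded,
    init: tuple[float, float, float] | None = None,
) -> SigmoidFit:
    """Least-squares logistic fit with analytic peak rate and lag time.

    Non-convergence (including degenerate flat series) is flagged on the
    result, never raised.
    """
    t = np.asarray(timepoints, dtype=float)
    d = np.asarray(degraded, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 timepoints")
    if t.shape != d.shape:
        raise ValueError("timepoints and values must align")
    if (d < 0).any():
        raise ValueError("degraded amounts must be non-negative")
    failed = SigmoidFit(float("nan"), float("nan"), float("nan"),
                        float("nan"), float("nan"), float("nan"), converged=False)
    if d.max() <= 0 or np.allclose(d, d[0]):
        return failed
    p0 = init if init is not None else _initial_guess(t, d)
    span = float(t.max() - t.min())
    bounds = (
        [1e-9, 1e-9, t.min() - span],
        [10.0 * d.max(), 1e3, t.max() + span],
    )
    p0 = tuple(np.clip(p0, bounds[0], bounds[1]))
    try:
        popt, _ = curve_fit(logistic, t, d, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        return failed
    K, r, t0 = (float(v) for v in popt)
    resid = d - logistic(t, K, r, t0)
    return SigmoidFit(
        K=K, r=r, t0=t0,
        peak_rate=r * K / 4.0,
        lag_time=t0,
        rss=float((resid**2).sum()),
        converged=True,
    )
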