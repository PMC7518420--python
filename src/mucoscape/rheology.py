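"""Half-gelation-temperature estimation from temperature sweeps.

Fits the four-parameter dose-response sigmoid (log-logistic in
temperature):

    response(T) = bottom + (top - bottom) / (1 + 10 ** (slope * (t_half - T)))

where ``t_half`` is the temperature of half-maximal gelation. Input may
be raw storage modulus or a pre-normalized gelation fraction; the fit
is identical (t_half and slope are invariant to positive scaling of the
response).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DegenerateDataError, ValidationError

MIN_POINTS = 6
_N_RESTARTS = 5


@dataclass
class GelationCurve:
    """A temperature sweep: strictly increasing temperatures, one response each."""

    temperature_c: np.ndarray
    response: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.temperature_c.ndim != 1 or self.response.ndim != 1:
            raise ValidationError("temperature and response must be 1D")
        if len(self.temperature_c) != len(self.response):
            raise ValidationError("temperature and response lengths differ")
        if len(self.temperature_c) < MIN_POINTS:
            raise ValidationError(f"need at least {MIN_POINTS} sweep points")
        if not np.all(np.diff(self.temperature_c) > 0):
            raise ValidationError("temperatures must be strictly increasing")
        if not np.all(np.isfinite(self.temperature_c)):
            raise ValidationError("temperatures must be finite")
        if not np.all(np.isfinite(self.response)) or np.any(self.response < 0):
            raise ValidationError("responses must be finite and >= 0")


@dataclass
class GelationFit:
    t_half_c: float
    hill_slope: float
    bottom: float
    top: float
    residual_sse: float
    converged: bool


def sigmoid(t, bottom, top, slope, t_half):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (t_half - t)))


def normalize_minmax(curve: GelationCurve) -> GelationCurve:
    """Min-max normalize the response to [0, 1]."""
    r = curve.response
    span = r.max() - r.min()
    if span == 0:
        raise DegenerateDataError("constant response cannot be normalized")
    return GelationCurve(
        temperature_c=curve.temperature_c,
        response=(r - r.min()) / span,
        label=curve.label,
    )


def _initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    bottom, top = float(y.min()), float(y.max())
    half = (bottom + top) / 2.0
    t_half = float(t[np.argmin(np.abs(y - half))])
    return np.array([bottom, top, 1.0, t_half])


def fit_gelation(curve: GelationCurve) -> GelationFit:
    """Least-squares dose-response fit; deterministic given the data.

    Initialization: bottom/top from the data range, t_half at the
    temperature nearest the half-range crossing, slope 1; on failure,
    up to five jittered restarts from a fixed seed. Non-convergence
    returns the best parameters found with ``converged=False``.
    """
    t, y = curve.temperature_c, curve.response
    if np.ptp(y) == 0:
        raise DegenerateDataError("response is constant; fit is undefined")

    t_lo, t_hi = float(t.min()), float(t.max())
    span = float(np.ptp(y))
    bounds = (
        [-np.inf, -np.inf, -100.0, t_lo],
        [np.inf, np.inf, 100.0, t_hi],
    )
    p0 = _initial_guess(t, y)
    rng = np.random.default_rng(0)

    best = None
    best_sse = np.inf
    converged = False
    for attempt in range(1 + _N_RESTARTS):
        guess = p0.copy()
        if attempt > 0:
            guess[0] += rng.normal(0, 0.05 * span)
            guess[1] += rng.normal(0, 0.05 * span)
            guess[2] = abs(rng.normal(1.0, 0.5)) + 1e-3
            guess[3] = float(np.clip(guess[3] + rng.normal(0, 2.0), t_lo, t_hi))
        try:
            popt, _ = curve_fit(
                sigmoid, t, y, p0=guess, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((sigmoid(t, *popt) - y) ** 2))
        if sse < best_sse:
            best_sse = sse
            best = popt
            converged = True
        if converged and attempt == 0:
            break

    if best is None:
        best = p0
        best_sse = float(np.sum((sigmoid(t, *best) - y) ** 2))

    bottom, top, slope, t_half = (float(v) for v in best)
    if top < bottom:  # equivalent reparameterization keeps bottom <= top
        bottom, top, slope = top, bottom, -slope
    return GelationFit(
        t_half_c=t_half,
        hill_slope=slope,
        bottom=bottom,
        top=top,
        residual_sse=best_sse,
        converged=converged,
    )


def compare_formulations(curve_a: GelationCurve, curve_b: GelationCurve) -> float:
    """Signed half-gelation-temperature shift t_half(a) - t_half(b) in C."""
    fit_a = fit_gelation(curve_a)
    fit_b = fit_gelation(curve_b)
    if not (fit_a.converged and fit_b.converged):
        raise DegenerateDataError("one or both gelation fits did not converge")
    return float(fit_a.t_half_c - fit_b.t_half_c)


def read_sweeps(path: str | Path) -> list[GelationCurve]:
    """Read sweeps from CSV with columns temperature_c, response[, series]."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "temperature_c" not in cols or "response" not in cols:
        raise ValidationError(
            "sweep CSV needs columns 'temperature_c' and 'response'"
        )
    curves = []
    if "series" in cols:
        for name, grp in df.groupby(cols["series"], sort=True):
            grp = grp.sort_values(cols["temperature_c"])
            curves.append(
                GelationCurve(
                    temperature_c=grp[cols["temperature_c"]].to_numpy(),
                    response=grp[cols["response"]].to_numpy(),
                    label=str(name),
                )
            )
    else:
        df = df.sort_values(cols["temperature_c"])
        curves.append(
            GelationCurve(
                temperature_c=df[cols["temperature_c"]].to_numpy(),
                response=df[cols["response"]].to_numpy(),
            )
        )
    return curves
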