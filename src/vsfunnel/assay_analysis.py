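"""Four-parameter logistic (4PL) dose-response analysis.

The sigmoid fitted to kinase-inhibition data is

    Y = Bottom + (Top - Bottom) / (1 + 10**((LogIC50 - X) * hillslope))

with X = log10(concentration).  At X = LogIC50 the response is the midpoint
(Top + Bottom)/2; the asymptotes are Bottom (X -> -inf, hillslope > 0) and
Top (X -> +inf).  Concentrations are handled internally in log10 nM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

#: Ten-fold dilution series commonly used for kinase IC50 assays (nM).
DEFAULT_DOSES_NM = (0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0)


@dataclass(frozen=True)
class FourPLParams:
    """Bottom/Top in response units, log_ic50 = log10(conc), hillslope unitless."""

    bottom: float
    top: float
    log_ic50: float
    hillslope: float

    def validate(self) -> None:
        if not np.isfinite([self.bottom, self.top, self.log_ic50, self.hillslope]).all():
            raise ValueError("non-finite parameter")
        if self.top == self.bottom:
            raise ValueError("top == bottom: curve is flat")
        if self.hillslope == 0:
            raise ValueError("hillslope must be nonzero")


@dataclass
class DoseResponseCurve:
    """x = log10(concentration), y = response (e.g. % inhibition)."""

    x: np.ndarray
    y: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")

    def averaged(self) -> "DoseResponseCurve":
        """Average replicate responses at identical doses."""
        ux = np.unique(self.x)
        uy = np.array([self.y[self.x == v].mean() for v in ux])
        return DoseResponseCurve(x=ux, y=uy)


def four_pl_response(x, p: FourPLParams):
    """Evaluate the 4PL curve; exponent clipped to avoid overflow."""
    x = np.asarray(x, dtype=float)
    expo = np.clip((p.log_ic50 - x) * p.hillslope, -300.0, 300.0)
    return p.bottom + (p.top - p.bottom) / (1.0 + 10.0**expo)


def _model(x, bottom, top, log_ic50, hillslope):
    expo = np.clip((log_ic50 - x) * hillslope, -300.0, 300.0)
    return bottom + (top - bottom) / (1.0 + 10.0**expo)


def fit_four_pl(
    c: DoseResponseCurve,
    init: FourPLParams | None = None,
    average_replicates: bool = True,
    fix_bottom: float | None = None,
    fix_top: float | None = None,
) -> tuple[FourPLParams, dict]:
    """Unweighted least-squares 4PL fit with self-starting defaults.

    Initial values: bottom = min(y), top = max(y), log_ic50 = x at the
    response closest to half-range, hillslope = 1.  ``fix_bottom``/``fix_top``
    pin an asymptote (e.g. 0/100 for percent inhibition).  Returns the
    parameters plus diagnostics (sse, converged, n_points).
    """
    curve = c.averaged() if average_replicates else c
    x, y = curve.x, curve.y
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct doses")
    if np.ptp(y) < 1e-12:
        raise ValueError("degenerate data: flat response")

    if init is None:
        half = (y.min() + y.max()) / 2.0
        init = FourPLParams(
            bottom=float(y.min()),
            top=float(y.max()),
            log_ic50=float(x[np.argmin(np.abs(y - half))]),
            hillslope=1.0,
        )

    if fix_bottom is not None and fix_top is not None:
        def f(x_, l, h):
            return _model(x_, fix_bottom, fix_top, l, h)
        p0 = [init.log_ic50, init.hillslope]
    elif fix_bottom is not None:
        def f(x_, t, l, h):
            return _model(x_, fix_bottom, t, l, h)
        p0 = [init.top, init.log_ic50, init.hillslope]
    elif fix_top is not None:
        def f(x_, b, l, h):
            return _model(x_, b, fix_top, l, h)
        p0 = [init.bottom, init.log_ic50, init.hillslope]
    else:
        f = _model
        p0 = [init.bottom, init.top, init.log_ic50, init.hillslope]

    converged = True
    try:
        popt, _ = curve_fit(f, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise ValueError(f"4PL fit did not converge: {exc}") from exc

    if fix_bottom is not None and fix_top is not None:
        params = FourPLParams(fix_bottom, fix_top, *popt)
    elif fix_bottom is not None:
        params = FourPLParams(fix_bottom, popt[0], popt[1], popt[2])
    elif fix_top is not None:
        params = FourPLParams(popt[0], fix_top, popt[1], popt[2])
    else:
        params = FourPLParams(*popt)
    resid = y - four_pl_response(x, params)
    diagnostics = {
        "sse": float(np.sum(resid**2)),
        "converged": converged,
        "n_points": int(len(x)),
    }
    return params, diagnostics


def ic50_from_fit(p: FourPLParams, unit: str = "nM") -> tuple[float, str]:
    """IC50 on the linear concentration scale, with its unit."""
    return float(10.0**p.log_ic50), unit


def percent_inhibition(signal, neg_ctrl: float, pos_ctrl: float):
    """Percent inhibition: 100 * (neg - signal) / (neg - pos).

    ``neg_ctrl`` is the uninhibited (full-signal) control, ``pos_ctrl`` the
    fully inhibited control.
    """
    if neg_ctrl == pos_ctrl:
        raise ValueError("controls are equal: percent inhibition undefined")
    return 100.0 * (neg_ctrl - np.asarray(signal, dtype=float)) / (neg_ctrl - pos_ctrl)
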