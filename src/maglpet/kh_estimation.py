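"""Mono-exponential estimation of the hydrolysis rate K_H from a TAC.

Once the plasma input is negligible (about 15 min post-injection) and CO2
efflux is much faster than hydrolysis (k5 >> K_H), total tissue activity
decays as A*exp(-a*t) with a = K_H.  The estimator fits that model to the
late washout window by non-linear least squares, with frame midpoints
converted to hours so the rate comes out directly in 1/h.

Also provides the derived ipsilateral/contralateral comparison arithmetic
used for stroke-model readouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .kinetics import TimeActivityCurve, ValidationError

__all__ = [
    "MonoExpFit",
    "fit_monoexp",
    "normalize_to_reference",
    "ips_cont_ratio",
    "percent_reduction",
]

DEFAULT_WINDOW = (15.0, 90.0)
RATE_BOUNDS_PER_H = (0.0, 20.0)


@dataclass(frozen=True)
class MonoExpFit:
    """Result of a mono-exponential washout fit.

    ``kh`` is the fitted clearance rate in 1/h, reported as K_H under the
    fast-CO2-efflux approximation (no k5 correction is applied).
    """

    amplitude: float
    kh: float
    window: tuple[float, float]
    residual_norm: float
    converged: bool
    n_points: int

    @property
    def rate_per_h(self) -> float:
        return self.kh


def _window_points(tac: TimeActivityCurve, window):
    lo, hi = window
    if hi <= lo:
        raise ValidationError("fit window must satisfy start < end")
    mid = tac.times
    sel = (mid >= lo) & (mid <= hi)
    return mid[sel], tac.values[sel], None if tac.weights is None else tac.weights[sel]


def fit_monoexp(tac: TimeActivityCurve, window=DEFAULT_WINDOW,
                use_duration_weights: bool = False) -> MonoExpFit:
    """Fit Activity(t) = A*exp(-a*t_hours) on the late washout window.

    Frames whose midpoints fall inside ``window`` (minutes) are used.
    Initialization comes from a log-linear regression on the positive
    in-window values; negative/zero values (possible under noise) are kept
    for the least-squares step but excluded from the initializer.  The
    rate is bounded to [0, 20] 1/h; flat data degenerates cleanly to a=0.
    """
    t_min, y, w = _window_points(tac, window)
    if t_min.size < 3:
        raise ValidationError(
            f"need >= 3 frames with midpoints inside {window}, got {t_min.size}"
        )
    if np.all(y <= 0):
        raise ValidationError("no positive activity inside the fit window")
    t_h = t_min / 60.0
    if use_duration_weights and w is None:
        w = tac.schedule.durations[(tac.times >= window[0]) & (tac.times <= window[1])]
    sw = np.sqrt(w) if w is not None else np.ones_like(y)

    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t_h[pos], np.log(y[pos]), 1)
        a0 = float(np.clip(-slope, *RATE_BOUNDS_PER_H))
        A0 = float(np.exp(intercept))
    else:  # pragma: no cover - needs pathological noise
        a0, A0 = 0.5, float(y[pos][0])

    def resid(p):
        A, a = p
        return sw * (y - A * np.exp(-a * t_h))

    sol = least_squares(resid, x0=[max(A0, 1e-12), a0],
                        bounds=([0.0, RATE_BOUNDS_PER_H[0]], [np.inf, RATE_BOUNDS_PER_H[1]]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    A, a = sol.x
    return MonoExpFit(
        amplitude=float(A), kh=float(a), window=(float(window[0]), float(window[1])),
        residual_norm=float(np.linalg.norm(sol.fun)), converged=bool(sol.success),
        n_points=int(t_min.size),
    )


def normalize_to_reference(tac: TimeActivityCurve, reference_time: float = 15.0) -> TimeActivityCurve:
    """Rescale a TAC so the frame containing ``reference_time`` reads 100 %.

    Normalization only rescales the amplitude, so the fitted exponential
    rate is unchanged.
    """
    idx = tac.schedule.frame_containing(reference_time)
    ref = tac.values[idx]
    if ref <= 0:
        raise ValidationError("reference-frame activity must be > 0")
    return TimeActivityCurve(tac.schedule, 100.0 * tac.values / ref, units="%max",
                             weights=tac.weights)


def ips_cont_ratio(kh_ips: float, kh_cont: float) -> float:
    """Ipsilateral / contralateral K_H ratio."""
    if kh_cont <= 0:
        raise ValidationError("contralateral K_H must be > 0")
    return kh_ips / kh_cont


def percent_reduction(kh_ips: float, kh_cont: float) -> float:
    """Percent by which the ipsilateral K_H is lower: 100*(1 - ips/cont)."""
    return 100.0 * (1.0 - ips_cont_ratio(kh_ips, kh_cont))
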