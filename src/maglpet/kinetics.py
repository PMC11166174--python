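"""Linear compartment model for a hydrolyzable covalent PET probe.

The probe enters tissue from plasma (K1), either washes back out (k2) or
binds covalently to its target enzyme (k3).  The covalent complex is slowly
hydrolyzed (K_H, reported in 1/h) to [11C]CO2, which leaves tissue rapidly
(k5) and may optionally re-enter from a plasma CO2 pool (k4):

    dC1/dt = K1*Cp(t) - (k2 + k3)*C1
    dC2/dt = k3*C1 - K_H*C2
    dC3/dt = K_H*C2 - k5*C3 + k4*Cp_CO2(t)

C1 is free/non-specifically bound probe, C2 the covalent complex, C3
dissolved CO2; measured tissue activity is C1+C2+C3.  Because k5 >> K_H in
brain, the late washout of total activity is governed by K_H alone, which
is what makes the mono-exponential shortcut in :mod:`maglpet.kh_estimation`
work.

The system is linear with biexponential forcing, so it is solved exactly:
the plasma exponentials are appended to the state vector and the augmented
autonomous system is propagated by matrix exponentials between breakpoints
(grid points, input delays, rate-switch times).  This sidesteps stiffness
from k5 >> K_H entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm

__all__ = [
    "C11_HALF_LIFE_MIN",
    "ValidationError",
    "RateConstants",
    "InputFunction",
    "FrameSchedule",
    "TimeActivityCurve",
    "CompartmentCurves",
    "solve_compartments",
    "simulate_tac",
    "frame_average",
    "to_suv",
    "decay_correct",
]

#: Physical half-life of carbon-11 in minutes.
C11_HALF_LIFE_MIN = 20.4


class ValidationError(ValueError):
    """Raised when inputs violate a model precondition."""


@dataclass(frozen=True)
class RateConstants:
    """Rate parameters of the tissue model.

    Parameters
    ----------
    K1 : float
        Delivery rate from plasma (ml ml^-1 min^-1, acts as a 1/min scaling
        of the plasma curve).
    k2 : float
        Efflux rate of free probe from tissue (1/min).
    k3 : float
        Covalent association rate to the enzyme (1/min).
    kh : float
        Hydrolysis rate of the covalent complex, in 1/h (the field's
        reporting convention); converted to 1/min internally.
    k4 : float
        Reuptake rate of CO2 from plasma (1/min).  Default 0: the CO2
        plasma pool is not modelled unless a second input curve is given.
    k5 : float
        Efflux rate of dissolved CO2 from tissue (1/min).  Default
        1.74 min^-1, the reported value for CO2 washout in healthy human
        brain.
    """

    K1: float
    k2: float
    k3: float
    kh: float
    k4: float = 0.0
    k5: float = 1.74

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "kh", "k4", "k5"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"rate constant {name} must be finite and >= 0, got {v!r}")

    @property
    def kh_per_min(self) -> float:
        """Hydrolysis rate in 1/min (kh is stored in 1/h)."""
        return self.kh / 60.0

    def with_kh_per_min(self, kh_per_min: float) -> "RateConstants":
        return replace(self, kh=60.0 * kh_per_min)


@dataclass(frozen=True)
class InputFunction:
    """Biexponential plasma concentration curve.

    Cp(t) = A1*exp(-lam1*(t-delay)) + A2*exp(-lam2*(t-delay)) for
    t >= delay and 0 before.  A negative second amplitude (with lam2 >
    lam1) gives the usual rise-and-fall bolus shape; the curve is
    validated to be non-negative everywhere.
    """

    A1: float
    A2: float
    lam1: float
    lam2: float
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.lam1 <= 0 or self.lam2 <= 0:
            raise ValidationError("decay rates lam1, lam2 must be > 0")
        if self.delay < 0:
            raise ValidationError("delay must be >= 0")
        # non-negativity: check t=delay, t->inf behaviour and the stationary point
        t_dense = self.delay + np.linspace(0.0, 300.0, 4001)
        if np.any(self(t_dense) < -1e-12 * max(abs(self.A1), abs(self.A2), 1.0)):
            raise ValidationError("input function is negative somewhere; Cp(t) must be >= 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        tau = t - self.delay
        out = np.where(
            tau >= 0,
            self.A1 * np.exp(-self.lam1 * np.clip(tau, 0, None))
            + self.A2 * np.exp(-self.lam2 * np.clip(tau, 0, None)),
            0.0,
        )
        return out if out.ndim else float(out)

    def peak(self) -> tuple[float, float]:
        """Analytic (time, value) of the curve maximum."""
        candidates = [self.delay]
        # stationary point of A1 e^{-l1 u} + A2 e^{-l2 u}: u* where derivative is 0
        num = -self.A2 * self.lam2
        den = self.A1 * self.lam1
        if den != 0 and num / den > 0 and self.lam1 != self.lam2:
            u = math.log(num / den) / (self.lam2 - self.lam1)
            if u > 0:
                candidates.append(self.delay + u)
        vals = [float(self(t)) for t in candidates]
        i = int(np.argmax(vals))
        return candidates[i], vals[i]

    def fraction_remaining(self, t: float = 15.0) -> float:
        """Cp(t) as a fraction of the peak value (the 15-min extinction check)."""
        _, peak = self.peak()
        if peak == 0:
            return 0.0
        return float(self(t)) / peak


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


class FrameSchedule:
    """Ordered, contiguous acquisition frames of a dynamic PET scan."""

    def __init__(self, start, end):
        start = _as_array(start)
        end = _as_array(end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise ValidationError("schedule needs equal-length, non-empty start/end arrays")
        if np.any(end - start <= 0):
            raise ValidationError("all frame durations must be > 0")
        if np.any(np.abs(start[1:] - end[:-1]) > 1e-9):
            raise ValidationError("frames must be contiguous and non-overlapping")
        self.start = start
        self.end = end

    @classmethod
    def from_durations(cls, durations: Sequence[float], t0: float = 0.0) -> "FrameSchedule":
        edges = t0 + np.concatenate([[0.0], np.cumsum(_as_array(durations))])
        return cls(edges[:-1], edges[1:])

    @classmethod
    def default(cls) -> "FrameSchedule":
        """The 26-frame, 90-min schedule: 1 min x 4, 2 min x 8, 5 min x 14."""
        return cls.from_durations([1.0] * 4 + [2.0] * 8 + [5.0] * 14)

    def __len__(self) -> int:
        return self.start.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrameSchedule)
            and np.array_equal(self.start, other.start)
            and np.array_equal(self.end, other.end)
        )

    def __repr__(self) -> str:
        return f"FrameSchedule({len(self)} frames, {self.start[0]:g}-{self.end[-1]:g} min)"

    @property
    def durations(self) -> np.ndarray:
        return self.end - self.start

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)

    @property
    def edges(self) -> np.ndarray:
        return np.concatenate([self.start, self.end[-1:]])

    def frame_containing(self, t: float) -> int:
        """Index of the frame whose [start, end) interval contains t."""
        if t < self.start[0] or t > self.end[-1]:
            raise ValidationError(f"time {t} outside schedule support")
        idx = int(np.searchsorted(self.end, t, side="right"))
        return min(idx, len(self) - 1)


@dataclass
class TimeActivityCurve:
    """Frame-binned activity measurements with their schedule."""

    schedule: FrameSchedule
    values: np.ndarray
    units: str = "SUV"
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = _as_array(self.values)
        if self.values.shape != (len(self.schedule),):
            raise ValidationError(
                f"TAC has {self.values.size} values for {len(self.schedule)} frames"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("TAC values must be finite")
        if self.weights is not None:
            self.weights = _as_array(self.weights)
            if self.weights.shape != self.values.shape:
                raise ValidationError("weights must match the number of frames")

    @property
    def times(self) -> np.ndarray:
        """Frame midpoints in minutes."""
        return self.schedule.midpoints

    def scaled(self, factor: float, units: str | None = None) -> "TimeActivityCurve":
        return TimeActivityCurve(
            self.schedule, self.values * factor, units or self.units, self.weights
        )


@dataclass
class CompartmentCurves:
    """Model solution sampled on a time grid (all curves in input units)."""

    t: np.ndarray
    C1: np.ndarray
    C2: np.ndarray
    C3: np.ndarray
    evaluator: Callable[[float], np.ndarray] | None = field(default=None, repr=False)

    @property
    def total(self) -> np.ndarray:
        return self.C1 + self.C2 + self.C3


RateSegments = Sequence[tuple[float, RateConstants]]


def _normalize_rates(rates: RateConstants | RateSegments) -> list[tuple[float, RateConstants]]:
    if isinstance(rates, RateConstants):
        return [(0.0, rates)]
    segs = [(float(t), rc) for t, rc in rates]
    if not segs:
        raise ValidationError("empty rate-segment list")
    if segs[0][0] != 0.0:
        raise ValidationError("first rate segment must start at t = 0")
    times = [t for t, _ in segs]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValidationError("rate-segment switch times must be strictly increasing")
    for _, rc in segs:
        if not isinstance(rc, RateConstants):
            raise ValidationError("rate segments must contain RateConstants")
    return segs


def _system_matrix(rc: RateConstants, inp: InputFunction, co2: InputFunction | None,
                   n_extra: int = 0) -> np.ndarray:
    """Augmented matrix over [C1, C2, C3, u1, u2(, v1, v2)(, I1, I2, I3)].

    u/v carry the plasma exponentials (amplitude folded into their initial
    condition at the delay breakpoint); the optional I rows accumulate
    running integrals of C1..C3 for exact frame averaging.
    """
    n = 5 + (2 if co2 is not None else 0)
    M = np.zeros((n + n_extra, n + n_extra))
    khm = rc.kh_per_min
    M[0, 0] = -(rc.k2 + rc.k3)
    M[1, 0] = rc.k3
    M[1, 1] = -khm
    M[2, 1] = khm
    M[2, 2] = -rc.k5
    M[0, 3] = rc.K1
    M[0, 4] = rc.K1
    M[3, 3] = -inp.lam1
    M[4, 4] = -inp.lam2
    if co2 is not None:
        M[2, 5] = rc.k4
        M[2, 6] = rc.k4
        M[5, 5] = -co2.lam1
        M[6, 6] = -co2.lam2
    if n_extra:
        for i in range(3):
            M[n + i, i] = 1.0
    return M


def _propagate(rates, inp, co2, eval_times, initial_state, with_integrals=False):
    """Propagate the augmented linear system; return states at eval_times.

    Returns an array of shape (len(eval_times), nstate); state layout as in
    :func:`_system_matrix`.
    """
    segs = _normalize_rates(rates)
    eval_times = _as_array(eval_times)
    if eval_times.ndim != 1 or eval_times.size == 0:
        raise ValidationError("need a 1-D, non-empty array of evaluation times")
    if np.any(np.diff(eval_times) <= 0):
        raise ValidationError("time grid must be strictly increasing")
    if eval_times[0] < 0:
        raise ValidationError("time grid must start at t >= 0")

    n_forcing = 2 + (2 if co2 is not None else 0)
    n_extra = 3 if with_integrals else 0
    nstate = 3 + n_forcing + n_extra

    delays = [inp.delay] + ([co2.delay] if co2 is not None else [])
    switch_times = [t for t, _ in segs[1:]]
    breaks = np.unique(np.concatenate([
        [0.0], eval_times, _as_array(delays), _as_array(switch_times)
    ]))
    breaks = breaks[breaks <= eval_times[-1] + 1e-15]

    x = np.zeros(nstate)
    x[:3] = _as_array(initial_state) if initial_state is not None else 0.0

    def activate_forcings(t, x):
        if abs(t - inp.delay) < 1e-15:
            x[3], x[4] = inp.A1, inp.A2
        if co2 is not None and abs(t - co2.delay) < 1e-15:
            x[5], x[6] = co2.A1, co2.A2

    seg_starts = [t for t, _ in segs]

    def rc_at(t):
        i = int(np.searchsorted(seg_starts, t + 1e-15)) - 1
        return segs[max(i, 0)][1]

    out = np.empty((eval_times.size, nstate))
    eval_idx = {round(t, 12): i for i, t in enumerate(eval_times)}

    t_prev = breaks[0]
    activate_forcings(t_prev, x)
    if round(t_prev, 12) in eval_idx:
        out[eval_idx[round(t_prev, 12)]] = x
    for t_next in breaks[1:]:
        M = _system_matrix(rc_at(t_prev), inp, co2, n_extra)
        x = expm(M * (t_next - t_prev)) @ x
        activate_forcings(t_next, x)
        key = round(t_next, 12)
        if key in eval_idx:
            out[eval_idx[key]] = x
        t_prev = t_next
    return out


def solve_compartments(
    rates: RateConstants | RateSegments,
    input_function: InputFunction,
    time_grid,
    initial_state=None,
    co2_input: InputFunction | None = None,
) -> CompartmentCurves:
    """Solve the tissue model on a time grid (minutes).

    ``rates`` may be a single :class:`RateConstants` or a list of
    ``(switch_time, RateConstants)`` segments (first at 0) for blocking and
    chase scenarios where k3 changes mid-scan.  ``co2_input`` enables the
    optional k4 reuptake pathway from a plasma CO2 curve.

    The returned curves carry an ``evaluator`` usable at arbitrary times,
    so downstream frame averaging is not limited to the grid.
    """
    time_grid = _as_array(time_grid)
    states = _propagate(rates, input_function, co2_input, time_grid, initial_state)
    # guard against tiny negative round-off
    C = np.clip(states[:, :3], 0.0, None)

    def evaluator(t: float) -> np.ndarray:
        # exact state at an arbitrary time (breakpoints are re-derived; the
        # matrix-exponential step is exact so grid resolution is irrelevant)
        s = _propagate(rates, input_function, co2_input,
                       np.array([max(float(t), 0.0)]), initial_state)
        return np.clip(s[-1, :3], 0.0, None)

    return CompartmentCurves(time_grid, C[:, 0], C[:, 1], C[:, 2], evaluator)


def simulate_tac(
    rates: RateConstants | RateSegments,
    input_function: InputFunction,
    schedule: FrameSchedule,
    initial_state=None,
    co2_input: InputFunction | None = None,
    units: str = "SUV",
) -> TimeActivityCurve:
    """Exact frame-averaged total-activity TAC of the tissue model.

    Frame means are computed from running integrals carried in the
    augmented state, so they are exact (to machine precision) rather than
    quadrature approximations.
    """
    edges = schedule.edges
    ts = edges if edges[0] == 0.0 else np.concatenate([[0.0], edges])
    states = _propagate(rates, input_function, co2_input, ts, initial_state,
                        with_integrals=True)
    integ = states[:, -3:].sum(axis=1)  # integral of C1+C2+C3
    if edges[0] != 0.0:
        integ = integ[1:]
    means = np.diff(integ) / schedule.durations
    return TimeActivityCurve(schedule, np.clip(means, 0.0, None), units=units)


def frame_average(curves_or_function, schedule: FrameSchedule) -> TimeActivityCurve:
    """Average a continuous activity signal over each acquisition frame.

    Accepts a callable f(t) or a :class:`CompartmentCurves` (whose total
    activity is used, via its exact evaluator when available, otherwise by
    linear interpolation of the sampled grid).
    """
    if len(schedule) == 0:  # pragma: no cover - FrameSchedule forbids this
        raise ValidationError("empty frame schedule")
    if callable(curves_or_function):
        f = curves_or_function
    elif isinstance(curves_or_function, CompartmentCurves):
        cc = curves_or_function
        if cc.evaluator is not None:
            f = lambda t: float(np.sum(cc.evaluator(t)))
        else:
            f = lambda t: float(np.interp(t, cc.t, cc.total))
    else:
        raise ValidationError("expected a callable or CompartmentCurves")
    vals = np.empty(len(schedule))
    for i, (a, b) in enumerate(zip(schedule.start, schedule.end)):
        integral, _ = quad(f, a, b, epsabs=1e-12, epsrel=1e-12, limit=200)
        vals[i] = integral / (b - a)
    return TimeActivityCurve(schedule, vals)


def to_suv(concentration, injected_dose: float, body_weight: float):
    """Standardized uptake value: concentration / (dose / body weight).

    Units must be consistent (e.g. kBq/ml, MBq dose, g weight with 1 g/ml
    tissue density); the result is dimensionless.
    """
    if injected_dose <= 0:
        raise ValidationError("injected dose must be > 0")
    if body_weight <= 0:
        raise ValidationError("body weight must be > 0")
    return np.asarray(concentration, dtype=float) / (injected_dose / body_weight)


def decay_correct(
    tac: TimeActivityCurve,
    half_life: float = C11_HALF_LIFE_MIN,
    reference_time: float = 0.0,
    invert: bool = False,
) -> TimeActivityCurve:
    """Decay-correct frame values to a reference time (default: injection).

    Each frame is scaled by 2**((t_mid - reference)/half_life); with
    ``invert=True`` the correction is undone (round trip is the identity).
    """
    if half_life <= 0:
        raise ValidationError("half-life must be > 0")
    factors = 2.0 ** ((tac.times - reference_time) / half_life)
    if invert:
        factors = 1.0 / factors
    return TimeActivityCurve(tac.schedule, tac.values * factors, tac.units, tac.weights)
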