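"""Simplified reference tissue model (SRTM) kinetics.

SRTM expresses a target-region time-activity curve as a function of a
reference-region curve (a region devoid of specific binding, the
cerebellum for raclopride-like tracers), avoiding arterial sampling:

    C_T(t) = R1 * C_R(t) + (k2 - R1 * k2a) * int_0^t C_R(u) exp(-k2a (t-u)) du

with k2a = k2 / (1 + BP_ND).  The three parameters are R1 (delivery
ratio, unitless), k2 (efflux rate, 1/min) and BP_ND (non-displaceable
binding potential, unitless) — BP_ND is the endpoint of interest.

Fitting uses the basis-function formulation: for each k2a on a
log-spaced grid the model is linear in (theta1, theta2) = (R1,
k2 - R1*k2a); the grid minimizer of the residual sum of squares is
refined by a bounded scalar search between its grid neighbors.

Times are minutes; activities Bq/mL; curves are decay-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, signal

log = logging.getLogger(__name__)

__all__ = [
    "FrameSchedule",
    "TAC",
    "SRTMParams",
    "SRTMFitConfig",
    "SRTMFitter",
    "ReferenceShape",
    "srtm_forward",
    "srtm_fit",
    "make_reference_tac",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous acquisition frames: start times and durations, minutes."""

    frame_starts: tuple[float, ...]
    frame_durations: tuple[float, ...]

    def __post_init__(self):
        starts = tuple(float(s) for s in self.frame_starts)
        durs = tuple(float(d) for d in self.frame_durations)
        if len(starts) != len(durs) or len(starts) == 0:
            raise ValueError("frame_starts and frame_durations must be equal-length, non-empty")
        if any(d <= 0 for d in durs):
            raise ValueError("frame durations must be > 0")
        for i in range(len(starts) - 1):
            if abs(starts[i] + durs[i] - starts[i + 1]) > 1e-9:
                raise ValueError(
                    f"schedule not contiguous at frame {i}: "
                    f"{starts[i]} + {durs[i]} != {starts[i + 1]}"
                )
        object.__setattr__(self, "frame_starts", starts)
        object.__setattr__(self, "frame_durations", durs)

    @classmethod
    def from_durations(cls, durations) -> "FrameSchedule":
        durs = tuple(float(d) for d in durations)
        starts = tuple(np.concatenate([[0.0], np.cumsum(durs)[:-1]]))
        return cls(starts, durs)

    @classmethod
    def default_dynamic(cls) -> "FrameSchedule":
        """The 27-frame, 90-min raclopride schedule:
        6 x 0.5 + 3 x 1 + 2 x 2 + 16 x 5 min."""
        return cls.from_durations([0.5] * 6 + [1.0] * 3 + [2.0] * 2 + [5.0] * 16)

    @property
    def n_frames(self) -> int:
        return len(self.frame_starts)

    @property
    def total_minutes(self) -> float:
        return self.frame_starts[-1] + self.frame_durations[-1]

    @property
    def frame_ends(self) -> tuple[float, ...]:
        return tuple(s + d for s, d in zip(self.frame_starts, self.frame_durations))

    @property
    def midpoints(self) -> np.ndarray:
        return np.asarray(self.frame_starts) + np.asarray(self.frame_durations) / 2.0


@dataclass(frozen=True)
class TAC:
    """A regional time-activity curve: one mean concentration per frame."""

    schedule: FrameSchedule
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 1 or len(vals) != self.schedule.n_frames:
            raise ValueError(
                f"values must be 1D with length {self.schedule.n_frames}, "
                f"got shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("TAC values must be finite")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class SRTMParams:
    """The SRTM triple: R1 (unitless), k2 (1/min), BP_ND (unitless)."""

    r1: float
    k2: float
    bp_nd: float

    def __post_init__(self):
        if self.k2 <= 0:
            raise ValueError(f"k2 must be > 0, got {self.k2}")
        if self.bp_nd <= -1:
            raise ValueError(f"bp_nd must be > -1, got {self.bp_nd}")

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.bp_nd)


@dataclass(frozen=True)
class ReferenceShape:
    """Difference-of-exponentials reference curve
    C_R(t) = A * (exp(-lam1 t) - exp(-lam2 t)), zero at t=0, single peak."""

    amplitude: float = 20000.0  # Bq/mL scale
    lam1: float = 0.03  # 1/min, slow washout
    lam2: float = 0.6  # 1/min, fast uptake

    def __post_init__(self):
        if not (self.lam2 > self.lam1 > 0):
            raise ValueError(
                f"need lam2 > lam1 > 0, got lam1={self.lam1}, lam2={self.lam2}"
            )

    def __call__(self, t):
        t = np.asarray(t, dtype=np.float64)
        return self.amplitude * (np.exp(-self.lam1 * t) - np.exp(-self.lam2 * t))

    @property
    def peak_time(self) -> float:
        return float(np.log(self.lam2 / self.lam1) / (self.lam2 - self.lam1))

    def frame_averages(self, schedule: FrameSchedule) -> np.ndarray:
        """Exact frame averages via the closed-form antiderivative."""

        def F(t):  # antiderivative of the curve
            t = np.asarray(t, dtype=np.float64)
            return self.amplitude * (
                -np.exp(-self.lam1 * t) / self.lam1 + np.exp(-self.lam2 * t) / self.lam2
            )

        a = np.asarray(schedule.frame_starts)
        b = np.asarray(schedule.frame_ends)
        return (F(b) - F(a)) / (b - a)


def make_reference_tac(
    shape: ReferenceShape | None = None, schedule: FrameSchedule | None = None
) -> TAC:
    """Synthesize the reference-region (cerebellum) TAC on a schedule."""
    if shape is None:
        shape = ReferenceShape()
    if schedule is None:
        schedule = FrameSchedule.default_dynamic()
    return TAC(schedule, shape.frame_averages(schedule))


def _fine_grid(schedule: FrameSchedule, dt: float) -> np.ndarray:
    n = int(round(schedule.total_minutes / dt))
    return np.arange(n + 1) * dt


def _exp_conv(cr: np.ndarray, k: float, dt: float) -> np.ndarray:
    """Trapezoidal causal convolution int_0^t C_R(u) exp(-k (t-u)) du on a
    uniform grid, computed via FFT convolution."""
    n = len(cr)
    e = np.exp(-k * dt * np.arange(n))
    full = signal.fftconvolve(cr, e)[:n]
    # trapezoid endpoint correction: subtract half the first and last terms
    return dt * (full - 0.5 * cr[0] * e - 0.5 * cr)


def _frame_average(curve: np.ndarray, t: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Time-average of a fine-grid curve over each frame (trapezoid)."""
    F = integrate.cumulative_trapezoid(curve, t, initial=0.0)
    dt = t[1] - t[0]
    ia = np.round(np.asarray(schedule.frame_starts) / dt).astype(int)
    ib = np.round(np.asarray(schedule.frame_ends) / dt).astype(int)
    return (F[ib] - F[ia]) / (np.asarray(schedule.frame_durations))


def srtm_forward(
    params: SRTMParams,
    ref,
    schedule: FrameSchedule,
    dt: float = 0.01,
) -> TAC:
    """Forward SRTM: frame-averaged target TAC from a reference curve.

    ``ref`` is either a callable ``t -> C_R(t)`` (e.g. a
    :class:`ReferenceShape`) or a pair ``(t_fine, values)`` on a uniform
    grid with step <= 0.05 min covering the schedule.
    """
    if dt > 0.05:
        raise ValueError(f"fine-grid dt must be <= 0.05 min, got {dt}")
    t = _fine_grid(schedule, dt)
    if callable(ref):
        cr = np.asarray(ref(t), dtype=np.float64)
    else:
        t_in, v_in = ref
        t_in = np.asarray(t_in, dtype=np.float64)
        if t_in[-1] < schedule.total_minutes - 1e-9:
            raise ValueError("reference grid does not cover the schedule")
        cr = np.interp(t, t_in, np.asarray(v_in, dtype=np.float64))
    k2a = params.k2a
    conv = _exp_conv(cr, k2a, dt)
    ct = params.r1 * cr + (params.k2 - params.r1 * k2a) * conv
    return TAC(schedule, _frame_average(ct, t, schedule))


@dataclass
class SRTMFitConfig:
    """Basis-function fit settings.

    k2a candidates are log-spaced on [k2a_min, k2a_max] (1/min); the
    grid winner is refined by a bounded scalar search between its
    neighbors.  Weights are uniform by default; ``weighting =
    "frame_duration"`` weights each frame by its duration.
    """

    k2a_min: float = 0.006
    k2a_max: float = 0.6
    n_basis: int = 128
    dt: float = 0.01
    weighting: str = "uniform"  # or "frame_duration"
    refine: bool = True

    def k2a_grid(self) -> np.ndarray:
        return np.geomspace(self.k2a_min, self.k2a_max, self.n_basis)


@dataclass
class SRTMFit:
    """Fit result: parameters plus diagnostics."""

    params: SRTMParams
    rss: float
    k2a: float
    fitted: np.ndarray
    at_boundary: bool


class SRTMFitter:
    """Estimator-style SRTM basis-function fitter.

    ``fit(target, ref)`` takes the target-region and reference-region
    TACs (same schedule) and exposes ``r1_``, ``k2_``, ``bp_nd_``,
    ``rss_``, ``k2a_`` and ``fitted_`` attributes.
    """

    def __init__(self, config: SRTMFitConfig | None = None):
        self.config = config

    def get_params(self) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "SRTMFitter":
        for k, v in params.items():
            if k != "config":
                raise ValueError(f"unknown parameter {k!r}")
            self.config = v
        return self

    def fit(self, target: TAC, ref: TAC) -> "SRTMFitter":
        cfg = self.config if self.config is not None else SRTMFitConfig()
        schedule = target.schedule
        if ref.schedule.n_frames != schedule.n_frames:
            raise ValueError("target and reference schedules differ")
        if schedule.n_frames < 3:
            raise ValueError("need at least 3 frames to fit 3 parameters")
        if np.all(ref.values == 0):
            raise ValueError("reference TAC is identically zero")

        t = _fine_grid(schedule, cfg.dt)
        # reconstruct a fine reference curve: zero at t=0, linear through
        # the frame midpoints, flat after the last midpoint
        mid = schedule.midpoints
        cr_fine = np.interp(t, np.concatenate([[0.0], mid]),
                            np.concatenate([[0.0], ref.values]))

        if cfg.weighting == "uniform":
            w = np.ones(schedule.n_frames)
        elif cfg.weighting == "frame_duration":
            w = np.asarray(schedule.frame_durations)
        else:
            raise ValueError(f"unknown weighting {cfg.weighting!r}")
        sw = np.sqrt(w)
        y = target.values * sw
        col1 = ref.values * sw  # theta1 column: the measured reference TAC

        def solve(k2a: float):
            basis = _frame_average(_exp_conv(cr_fine, k2a, cfg.dt), t, schedule)
            A = np.column_stack([col1, basis * sw])
            theta, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ theta
            return float(resid @ resid), theta, basis

        grid = cfg.k2a_grid()
        rss = np.array([solve(k)[0] for k in grid])
        best = int(np.argmin(rss))
        k2a_best = float(grid[best])
        if cfg.refine and 0 < best < len(grid) - 1:
            res = optimize.minimize_scalar(
                lambda lk: solve(float(np.exp(lk)))[0],
                bounds=(np.log(grid[best - 1]), np.log(grid[best + 1])),
                method="bounded",
                options={"xatol": 1e-8},
            )
            k2a_best = float(np.exp(res.x))
        at_boundary = best in (0, len(grid) - 1)
        if at_boundary:
            log.warning(
                "selected k2a %.4g is at the basis-grid boundary "
                "[%.4g, %.4g]; consider widening the grid",
                k2a_best, cfg.k2a_min, cfg.k2a_max,
            )
        rss_best, theta, basis = solve(k2a_best)
        r1 = float(theta[0])
        k2 = float(theta[1] + theta[0] * k2a_best)
        bp = k2 / k2a_best - 1.0
        fitted = theta[0] * ref.values + theta[1] * basis

        self.r1_ = r1
        self.k2_ = k2
        self.bp_nd_ = float(bp)
        self.k2a_ = k2a_best
        self.rss_ = rss_best
        self.fitted_ = fitted
        self.at_boundary_ = at_boundary
        self.result_ = SRTMFit(
            SRTMParams(r1, k2, bp), rss_best, k2a_best, fitted, at_boundary
        )
        return self


def srtm_fit(target: TAC, ref: TAC, config: SRTMFitConfig | None = None) -> SRTMFit:
    """Fit SRTM to a target/reference TAC pair; see :class:`SRTMFitter`."""
    return SRTMFitter(config).fit(target, ref).result_
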