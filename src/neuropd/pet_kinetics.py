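"""Simplified reference tissue model (SRTM) on framed time-activity curves.

The SRTM expresses a target-region curve in terms of a reference-region
curve devoid of specific binding:

    C_T(t) = R1 * C_R(t) + (k2 - R1 * k2a) * [C_R (x) exp(-k2a t)](t),

with delivery ratio R1, reference efflux-related rate k2 (1/min), apparent
efflux k2a = k2 / (1 + BP_ND) and binding potential BP_ND.  Fitting uses
the basis-function approach: for each candidate k2a the convolution basis
is precomputed and the remaining two coefficients solve a linear
least-squares problem; the k2a minimising the (frame-duration weighted)
residual sum of squares wins and is then polished by a bounded 1-D search.

All curve arithmetic treats the continuous reference curve as piecewise
linear through the frame-midpoint values (anchored at zero activity at
injection), and model frames as averages of the continuous prediction
over the frame interval; this avoids discretisation bias on coarse late
frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "ScanMeta",
    "SRTMParams",
    "default_90min_schedule",
    "suv",
    "srtm_forward",
    "srtm_fit_basis",
    "default_theta_grid",
]

_SUBSTEPS = 8  # quadrature points per frame for frame averaging


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames (seconds)."""

    start_s: np.ndarray
    dur_s: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.dur_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "dur_s", dur)
        if start.ndim != 1 or start.shape != dur.shape or start.size == 0:
            raise ValueError("start and duration arrays must be 1-D and matched")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        ends = start + dur
        if np.any(np.diff(start) <= 0) or np.any(start[1:] < ends[:-1] - 1e-9):
            raise ValueError("frames must be sorted and non-overlapping")

    @classmethod
    def from_durations(cls, durations_s):
        dur = np.asarray(durations_s, dtype=float)
        start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
        return cls(start, dur)

    @property
    def n_frames(self):
        return self.start_s.size

    @property
    def mid_s(self):
        return self.start_s + self.dur_s / 2.0

    @property
    def mid_min(self):
        return self.mid_s / 60.0

    @property
    def end_s(self):
        return self.start_s + self.dur_s


def default_90min_schedule() -> FrameSchedule:
    """26-frame 90-min dynamic schedule: 8x15, 3x60, 5x120, 5x300, 5x600 s."""
    return FrameSchedule.from_durations(
        [15.0] * 8 + [60.0] * 3 + [120.0] * 5 + [300.0] * 5 + [600.0] * 5
    )


@dataclass
class TimeActivityCurve:
    """Framed activity concentrations (kBq/mL) for one region and scan."""

    schedule: FrameSchedule
    activity_kbq_ml: np.ndarray
    region: str = ""
    scan_id: str = ""

    def __post_init__(self):
        act = np.asarray(self.activity_kbq_ml, dtype=float)
        if act.shape != (self.schedule.n_frames,):
            raise ValueError("activity length must match the frame count")
        if not np.all(np.isfinite(act)):
            raise ValueError("activities must be finite")
        self.activity_kbq_ml = act


@dataclass(frozen=True)
class ScanMeta:
    injected_mbq: float
    body_weight_kg: float
    reference_region: str = "cerebellum"

    def __post_init__(self):
        if self.injected_mbq <= 0:
            raise ValueError("injected activity must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")


@dataclass
class SRTMParams:
    r1: float
    k2: float          # 1/min
    bp_nd: float
    rss: float = float("nan")
    at_grid_boundary: bool = False
    negative_bp: bool = False

    @property
    def k2a(self):
        return self.k2 / (1.0 + self.bp_nd)

    def __post_init__(self):
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if self.bp_nd <= -1:
            raise ValueError("BP_ND must exceed -1")


def suv(activity_kbq_ml, meta: ScanMeta):
    """Standardized uptake value: activity / (injected activity / body weight)."""
    act = np.asarray(activity_kbq_ml, dtype=float)
    out = act / (meta.injected_mbq / meta.body_weight_kg)
    return float(out) if np.isscalar(activity_kbq_ml) else out


# -- continuous-time machinery ------------------------------------------------

def _fine_grid(schedule: FrameSchedule):
    """Quadrature nodes (min) and per-frame node slices.

    Each frame is subdivided into ``_SUBSTEPS`` panels; t = 0 is always a
    node so convolutions start at injection.
    """
    nodes = [np.array([0.0])]
    slices = []
    pos = 1
    last_end = 0.0
    for s, d in zip(schedule.start_s, schedule.dur_s):
        pts = np.linspace(s, s + d, _SUBSTEPS + 1)
        if abs(s - last_end) < 1e-9:  # contiguous: start node already present
            nodes.append(pts[1:])
            slices.append(slice(pos - 1, pos + _SUBSTEPS))
            pos += _SUBSTEPS
        else:  # gap before this frame
            nodes.append(pts)
            slices.append(slice(pos, pos + _SUBSTEPS + 1))
            pos += _SUBSTEPS + 1
        last_end = s + d
    return np.concatenate(nodes) / 60.0, slices


def _frame_average(values, grid_min, slices, schedule):
    """Trapezoidal frame means of a curve sampled on the fine grid."""
    out = np.empty(schedule.n_frames)
    for i, sl in enumerate(slices):
        out[i] = np.trapezoid(values[sl], grid_min[sl]) / (schedule.dur_s[i] / 60.0)
    return out


def _ref_on_grid(reference: TimeActivityCurve, grid_min):
    """Reference curve interpolated piecewise-linearly through midpoints.

    Anchored at zero at injection time; held at the last frame value beyond
    the final midpoint.
    """
    mids = reference.schedule.mid_min
    vals = reference.activity_kbq_ml
    xp = np.concatenate([[0.0], mids])
    fp = np.concatenate([[0.0], vals])
    return np.interp(grid_min, xp, fp)


def _exp_conv(ref_fine, grid_min, theta):
    """y(t) = int_0^t C_R(u) exp(-theta (t-u)) du on the fine grid.

    Exact for a piecewise-linear integrand; stable for small theta via a
    series expansion of (1 - exp(-theta dt)) / theta.
    """
    n = grid_min.size
    y = np.zeros(n)
    dt = np.diff(grid_min)
    e = np.exp(-theta * dt)
    # phi = (1 - e)/theta, psi = (dt - phi)/theta, with series for small x
    x = theta * dt
    small = x < 1e-4
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(small, dt * (1 - x / 2 + x * x / 6),
                       (1 - e) / max(theta, 1e-300))
        # (dt - phi)/theta cancels catastrophically for small theta*dt
        psi = np.where(small, dt * dt * (0.5 - x / 6 + x * x / 24),
                       (dt - phi) / max(theta, 1e-300))
    a = ref_fine[:-1]
    b = np.diff(ref_fine) / dt
    inc = a * phi + b * psi
    for i in range(1, n):
        y[i] = y[i - 1] * e[i - 1] + inc[i - 1]
    return y


def _bases(reference: TimeActivityCurve, theta):
    """Frame-averaged (reference, convolution) design columns for one theta.

    The delivery column is the measured frame values themselves (a TAC
    frame *is* the frame average of the underlying curve); only the
    convolution term requires the continuous piecewise-linear interpolant.
    """
    grid, slices = _fine_grid(reference.schedule)
    ref_fine = _ref_on_grid(reference, grid)
    conv_fine = _exp_conv(ref_fine, grid, theta)
    sched = reference.schedule
    return (reference.activity_kbq_ml,
            _frame_average(conv_fine, grid, slices, sched))


def srtm_forward(reference: TimeActivityCurve, params: SRTMParams,
                 region: str = "", scan_id: str = "") -> TimeActivityCurve:
    """Forward-simulate a target TAC from a reference TAC and SRTM parameters."""
    theta = params.k2a
    if theta <= 0:
        raise ValueError("apparent efflux k2a must be positive")
    ref_avg, conv_avg = _bases(reference, theta)
    target = params.r1 * ref_avg + (params.k2 - params.r1 * theta) * conv_avg
    return TimeActivityCurve(schedule=reference.schedule,
                             activity_kbq_ml=target,
                             region=region or "target", scan_id=scan_id)


def default_theta_grid(n=100, lo=0.006, hi=0.6):
    """Logarithmic candidate grid for the apparent efflux k2a (1/min)."""
    return np.geomspace(lo, hi, n)


def _wls_rss(theta, reference, y, w):
    ref_avg, conv_avg = _bases(reference, theta)
    X = np.column_stack([ref_avg, conv_avg])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    r = y - X @ coef
    return float(w @ (r * r)), coef


def srtm_fit_basis(target: TimeActivityCurve, reference: TimeActivityCurve,
                   theta_grid=None, weights="duration",
                   refine: bool = True) -> SRTMParams:
    """Basis-function SRTM fit.

    For each candidate k2a the convolution basis is formed and the two
    linear coefficients (of C_R and of the basis) are solved by weighted
    least squares; the winning k2a is refined by a bounded scalar search
    between its grid neighbours.  Frame weights default to frame duration
    (a count-statistics proxy); pass ``None`` or equal weights for an
    unweighted fit.
    """
    if target.schedule.n_frames < 3:
        raise ValueError("need at least 3 frames")
    if target.schedule.n_frames != reference.schedule.n_frames:
        raise ValueError("target and reference must share the frame schedule")
    thetas = np.asarray(theta_grid if theta_grid is not None
                        else default_theta_grid(), dtype=float)
    if np.any(thetas <= 0):
        raise ValueError("theta grid must be positive")
    thetas = np.sort(thetas)

    if weights is None:
        w = np.ones(target.schedule.n_frames)
    elif isinstance(weights, str) and weights == "duration":
        w = target.schedule.dur_s / target.schedule.dur_s.mean()
    else:
        w = np.asarray(weights, dtype=float)

    y = target.activity_kbq_ml
    rss = np.empty(thetas.size)
    for i, th in enumerate(thetas):
        rss[i], _ = _wls_rss(th, reference, y, w)
    best = int(np.argmin(rss))
    at_boundary = best in (0, thetas.size - 1)

    theta_hat = thetas[best]
    if refine:
        lo = thetas[max(best - 1, 0)]
        hi = thetas[min(best + 1, thetas.size - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda th: _wls_rss(th, reference, y, w)[0],
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-12})
            if res.fun <= rss[best]:
                theta_hat = float(res.x)

    final_rss, coef = _wls_rss(theta_hat, reference, y, w)
    r1 = float(coef[0])
    k2 = float(coef[1] + r1 * theta_hat)
    bp = k2 / theta_hat - 1.0
    return SRTMParams(r1=r1, k2=k2, bp_nd=bp, rss=final_rss,
                      at_grid_boundary=at_boundary, negative_bp=bp < 0)
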