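"""Rotation-ramp analysis: kinematic mapping, events and retention forces.

The centrifugal stage ramps the rotation speed RS linearly in time (default
1 rpm/s up to 100 rpm); a droplet at radius r then experiences the body
acceleration ``alpha_c = omega^2 r`` with ``omega = 2 pi RS / 60``.  At
r = 0.25 m this reaches 27.4 m/s^2 at 100 rpm and matches gravity near
60 rpm.

Measurement series (edge positions, contact angles) are smoothed by a mild
centered running average, depinning onsets are detected as the first
persistent displacement of an edge beyond a small tolerance, frames are
classified into static / leaning / spreading / sliding / runoff regimes, the
advancing and receding contact angles are read from the smoothed angle
series at the respective onsets, and the sliding-onset retention force is
estimated with the Furmidge relation
``F = k gamma w (cos theta_rec - cos theta_adv)`` against the centrifugal
driving force ``F_c = rho V alpha_c``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

REGIMES = ("static", "leaning", "spreading", "sliding", "runoff")

#: default depinning displacement tolerance, mm (below the figure-resolution
#: motion of a pinned edge, above pixel noise)
DEPIN_EPSILON = 0.1
#: default persistence, frames (0.5 s at 10 fps)
DEPIN_PERSISTENCE = 5
#: default running-average window, frames
SMOOTH_WINDOW = 11
#: tolerance on angle divergence for the leaning label, degrees
LEAN_TOL = 2.0


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class RampConfig:
    """Ramp protocol: linear RS increase, saturating at ``max_rs``."""

    ramp_rate: float = 1.0   # rpm/s
    start_rs: float = 0.0    # rpm
    max_rs: float = 100.0    # rpm
    radius: float = 0.25     # m, droplet distance from the rotation axis
    fps: float = 10.0

    def __post_init__(self) -> None:
        if not self.ramp_rate > 0:
            raise ValueError("ramp_rate must be positive")
        if not self.radius > 0:
            raise ValueError("radius must be positive")


@dataclass
class RampPoint:
    """One instant of the ramp with derived kinematic quantities."""

    time: float
    RS: float            # rpm
    f: float             # Hz
    omega: float         # rad/s
    alpha_c: float       # m/s^2

    @classmethod
    def at_time(cls, t: float, ramp: RampConfig) -> "RampPoint":
        rs = rs_at_time(t, ramp)
        f = rs / 60.0
        omega = 2.0 * np.pi * f
        return cls(time=t, RS=rs, f=f, omega=omega,
                   alpha_c=omega ** 2 * ramp.radius)


@dataclass
class WettingEvents:
    """Depinning onsets (rpm, None = never), onset angles and regime labels."""

    front_depin_rs_whole: Optional[float] = None
    front_depin_rs_bulky: Optional[float] = None
    rear_depin_rs_whole: Optional[float] = None
    rear_depin_rs_bulky: Optional[float] = None
    theta_adv: Optional[float] = None
    theta_rec: Optional[float] = None
    regimes: list[str] = field(default_factory=list)


@dataclass
class RetentionInput:
    """Physical inputs for the force balance (SI units)."""

    gamma: float = 0.072      # N/m, surface tension
    w: float = 2e-3           # m, contact-line width
    k_shape: float = 1.0      # dimensionless Furmidge prefactor
    rho: float = 1000.0       # kg/m^3
    V: float = 10e-9          # m^3 (10 uL)

    def __post_init__(self) -> None:
        for name in ("gamma", "w", "k_shape", "rho", "V"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# kinematic mapping
# ---------------------------------------------------------------------------

def rs_at_time(t: float, ramp: RampConfig) -> float:
    """Rotation speed (rpm) at time t: start + rate*t, clamped at max_rs."""
    if t < 0:
        raise ValueError("time must be non-negative")
    return float(min(ramp.start_rs + ramp.ramp_rate * t, ramp.max_rs))


def centrifugal_acceleration(rs: float, radius: float = 0.25) -> float:
    """Centrifugal acceleration alpha_c = (2 pi RS/60)^2 r, in m/s^2."""
    if rs < 0:
        raise ValueError("rotation speed must be non-negative")
    if not radius > 0:
        raise ValueError("radius must be positive")
    omega = 2.0 * np.pi * rs / 60.0
    return float(omega ** 2 * radius)


# ---------------------------------------------------------------------------
# series processing and event detection
# ---------------------------------------------------------------------------

def smooth_series(series: Sequence[float], window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered running average; the window shrinks symmetrically at edges.

    ``window`` must be odd; window 1 is the identity.  NaNs are ignored
    within each window.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    x = np.asarray(series, dtype=float)
    n = len(x)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        seg = x[i - k:i + k + 1]
        good = np.isfinite(seg)
        out[i] = np.mean(seg[good]) if good.any() else np.nan
    return out


def detect_depinning(positions: Sequence[float], rs: Sequence[float],
                     epsilon: float = DEPIN_EPSILON,
                     persistence: int = DEPIN_PERSISTENCE) -> Optional[float]:
    """Onset RS of edge motion, or None if the edge never depins.

    The onset is the rotation speed of the first frame whose displacement
    from the initial (pre-ramp) position exceeds ``epsilon`` (mm) and stays
    exceeded for ``persistence`` consecutive frames.  The initial position
    is the mean of the first ``persistence`` frames, which suppresses
    single-frame noise.
    """
    x = np.asarray(positions, dtype=float)
    r = np.asarray(rs, dtype=float)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    if len(x) < persistence:
        raise ValueError(f"series of length {len(x)} is shorter than the "
                         f"persistence of {persistence} frames")
    x0 = float(np.nanmean(x[:persistence]))
    exceeded = np.abs(x - x0) > epsilon
    n = len(x)
    runlen = np.zeros(n + 1, dtype=int)  # forward run length from each frame
    for i in range(n - 1, -1, -1):
        runlen[i] = runlen[i + 1] + 1 if exceeded[i] else 0
    idx = np.nonzero(runlen[:n] >= persistence)[0]
    return float(r[idx[0]]) if len(idx) else None


def classify_regimes(events: WettingEvents, rs: Sequence[float],
                     theta_f: Sequence[float], theta_r: Sequence[float],
                     x_front: Sequence[float],
                     fov_limit: Optional[float] = None,
                     lean_tol: float = LEAN_TOL) -> list[str]:
    """Per-frame regime labels: static/leaning/spreading/sliding/runoff.

    Static until the front/rear angle difference grows beyond ``lean_tol``
    (deg) relative to its initial value; leaning until the front edge
    depins; spreading while the rear stays pinned; sliding once both rear
    and front have depinned; runoff once the front edge passes ``fov_limit``
    (mm) or its position is lost (NaN).
    """
    rs = np.asarray(rs, dtype=float)
    tf = np.asarray(theta_f, dtype=float)
    tr = np.asarray(theta_r, dtype=float)
    xf = np.asarray(x_front, dtype=float)
    front_on = events.front_depin_rs_whole
    if front_on is None:
        front_on = events.front_depin_rs_bulky
    rear_on = events.rear_depin_rs_whole

    div0 = abs(tf[0] - tr[0]) if np.isfinite(tf[0]) and np.isfinite(tr[0]) else 0.0
    labels: list[str] = []
    leaning_started = False
    for i in range(len(rs)):
        if (fov_limit is not None and np.isfinite(xf[i]) and xf[i] > fov_limit) \
                or not np.isfinite(xf[i]):
            labels.append("runoff")
            continue
        if rear_on is not None and rs[i] >= rear_on:
            labels.append("sliding")
            continue
        if front_on is not None and rs[i] >= front_on:
            labels.append("spreading")
            continue
        if not leaning_started and np.isfinite(tf[i]) and np.isfinite(tr[i]) \
                and abs(tf[i] - tr[i]) - div0 > lean_tol:
            leaning_started = True
        labels.append("leaning" if leaning_started else "static")
    return labels


def onset_angles(events: WettingEvents, rs: Sequence[float],
                 theta_front: Sequence[float], theta_rear: Sequence[float],
                 window: int = SMOOTH_WINDOW
                 ) -> tuple[Optional[float], Optional[float]]:
    """(theta_adv, theta_rec): smoothed angles at the depinning onsets.

    The advancing angle is the smoothed front angle at the front depinning
    onset; the receding angle is the smoothed rear angle at the rear
    depinning onset (whole-droplet rear when it depins, otherwise the bulky
    rear).  Angles without an onset are None.
    """
    rs = np.asarray(rs, dtype=float)
    tf_s = smooth_series(theta_front, window)
    tr_s = smooth_series(theta_rear, window)

    def at_onset(onset: Optional[float], series: np.ndarray) -> Optional[float]:
        if onset is None:
            return None
        idx = np.nonzero(rs >= onset)[0]
        if len(idx) == 0:
            return None
        return float(series[idx[0]])

    front_on = events.front_depin_rs_whole
    if front_on is None:
        front_on = events.front_depin_rs_bulky
    rear_on = events.rear_depin_rs_whole
    if rear_on is None:
        rear_on = events.rear_depin_rs_bulky
    return at_onset(front_on, tf_s), at_onset(rear_on, tr_s)


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def furmidge_force(inp: RetentionInput, theta_adv: float, theta_rec: float) -> float:
    """Furmidge retention force F = k gamma w (cos theta_rec - cos theta_adv), N.

    Angles in degrees, in [0, 180).  A receding angle above the advancing
    angle is non-physical hysteresis; the (negative) force is still returned
    but a warning is emitted.
    """
    for name, th in (("theta_adv", theta_adv), ("theta_rec", theta_rec)):
        if not 0 <= th < 180:
            raise ValueError(f"{name} must lie in [0, 180) degrees")
    force = inp.k_shape * inp.gamma * inp.w * (
        np.cos(np.deg2rad(theta_rec)) - np.cos(np.deg2rad(theta_adv)))
    if force < 0:
        warnings.warn("theta_rec > theta_adv: negative retention force "
                      "(non-physical hysteresis)", stacklevel=2)
    return float(force)


def body_force(inp: RetentionInput, alpha_c: float) -> float:
    """Centrifugal driving force F_c = rho V alpha_c, in N."""
    if alpha_c < 0:
        raise ValueError("alpha_c must be non-negative")
    return float(inp.rho * inp.V * alpha_c)


# ---------------------------------------------------------------------------
# series-level pipeline
# ---------------------------------------------------------------------------

def analyze_ramp(rs: Sequence[float], theta_f: Sequence[float],
                 theta_r: Sequence[float], x_front: Sequence[float],
                 x_rear: Sequence[float],
                 x_front_bulky: Optional[Sequence[float]] = None,
                 x_rear_bulky: Optional[Sequence[float]] = None,
                 epsilon: float = DEPIN_EPSILON,
                 persistence: int = DEPIN_PERSISTENCE,
                 smooth_window: int = SMOOTH_WINDOW,
                 fov_limit: Optional[float] = None,
                 retention: Optional[RetentionInput] = None
                 ) -> tuple[WettingEvents, dict]:
    """Detect events on a measurement series and assemble the results.

    Edge-position series are smoothed before onset detection; regime labels
    and onset angles are derived from the detected events.  When a
    ``RetentionInput`` is given and both onset angles exist, the Furmidge
    retention force and the driving force at the sliding onset are also
    reported in the returned info dict.
    """
    sm = lambda v: smooth_series(v, smooth_window)  # noqa: E731
    events = WettingEvents(
        front_depin_rs_whole=detect_depinning(sm(x_front), rs, epsilon, persistence),
        rear_depin_rs_whole=detect_depinning(sm(x_rear), rs, epsilon, persistence),
    )
    def has_data(v) -> bool:
        return v is not None and np.isfinite(np.asarray(v, dtype=float)).any()

    if has_data(x_front_bulky):
        events.front_depin_rs_bulky = detect_depinning(
            sm(x_front_bulky), rs, epsilon, persistence)
    if has_data(x_rear_bulky):
        events.rear_depin_rs_bulky = detect_depinning(
            sm(x_rear_bulky), rs, epsilon, persistence)
    events.theta_adv, events.theta_rec = onset_angles(
        events, rs, theta_f, theta_r, smooth_window)
    events.regimes = classify_regimes(events, rs, theta_f, theta_r,
                                      x_front, fov_limit)
    info: dict = {}
    if retention is not None and events.theta_adv is not None \
            and events.theta_rec is not None:
        info["furmidge_force_N"] = furmidge_force(
            retention, events.theta_adv, events.theta_rec)
        rear_on = events.rear_depin_rs_whole
        if rear_on is None:
            rear_on = events.rear_depin_rs_bulky
        if rear_on is not None:
            info["driving_force_at_sliding_N"] = body_force(
                retention, centrifugal_acceleration(rear_on))
    return events, info
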