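"""Wetting parameters from droplet contours.

From the two segmented contours this module derives the standard 2-D
descriptors of a deformed sessile droplet:

* top view — direct least-squares ellipse fits for the whole droplet and the
  dark bulky region, the major axis ``A_max = 2a``, its in-plane deviation
  ``alpha_A`` from the direction of motion, the x-projected lengths
  ``L_T1``/``L_T2`` and the ellipse areas;
* side view — per-region baselines (the whole-droplet and bulky-region
  baselines are independent and need not coincide), contact points, droplet
  lengths ``L_s1``/``L_s2``, height, apparent front/rear contact angles
  ``theta_f1``/``theta_r1``/``theta_f2``/``theta_r2``, and a solid-of-
  revolution volume estimate.

Contact angles are *apparent* angles between the substrate baseline and the
local tangent of the contour at the contact point; the tangent is estimated
by a quadratic fit, in arc-length parametrization, to the contour arc within
a window of the contact point (default 10% of the region's contact length),
which remains single-valued for angles beyond 90 deg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from skimage.measure import EllipseModel

from . import segmentation as seg
from .frames import Frame
from .segmentation import AxisPositions, SegmentationResult, ThresholdPair

#: default tangent-fit window, as a fraction of the region's contact length
ANGLE_WINDOW = 0.10


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class EllipseFit:
    """Ellipse parameters in mm: center, semi-axes a >= b, orientation.

    ``phi_deg`` is the major-axis angle from the +x axis, normalized to
    (-90, 90].  ``A_max = 2a`` is the droplet major axis; ``alpha_A`` is the
    angular deviation of the major axis from the direction of motion.
    """

    center: tuple[float, float]
    a: float
    b: float
    phi_deg: float

    def __post_init__(self) -> None:
        if not self.b > 0 or self.a < self.b:
            raise ValueError("need a >= b > 0")
        if not -90 < self.phi_deg <= 90:
            raise ValueError("phi_deg must lie in (-90, 90]")

    @property
    def A_max(self) -> float:
        return 2.0 * self.a

    @property
    def alpha_A(self) -> float:
        return self.phi_deg

    @property
    def area(self) -> float:
        return float(np.pi * self.a * self.b)


@dataclass
class Baseline:
    """Substrate line in the side view, two (x, y) endpoints in mm.

    The whole-droplet and bulky-region baselines are independent; on real
    images they may differ by a few degrees due to optical effects.
    """

    p0: tuple[float, float]
    p1: tuple[float, float]
    applies_to: str = "whole"

    def __post_init__(self) -> None:
        if np.allclose(self.p0, self.p1):
            raise ValueError("baseline endpoints must be distinct")
        if self.applies_to not in ("whole", "bulky"):
            raise ValueError("applies_to must be 'whole' or 'bulky'")

    def frame_vectors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(origin, along-unit, up-unit) of the baseline frame.

        ``along`` points in +x (droplet motion); ``up`` points away from the
        substrate (toward smaller image y).
        """
        p0 = np.asarray(self.p0, dtype=float)
        u = np.asarray(self.p1, dtype=float) - p0
        u = u / np.linalg.norm(u)
        if u[0] < 0:
            u = -u
        n = np.array([u[1], -u[0]])  # up in image coordinates (y down)
        return p0, u, n


@dataclass
class GeometryMeasurement:
    """Per-frame 2-D wetting parameters (angles deg, lengths mm, areas mm^2).

    Suffix 1 refers to the whole droplet (body + tail), suffix 2 to the dark
    bulky region.  Missing quantities are NaN.
    """

    theta_f1: float = np.nan
    theta_r1: float = np.nan
    theta_f2: float = np.nan
    theta_r2: float = np.nan
    L_s1: float = np.nan
    L_s2: float = np.nan
    L_T1: float = np.nan
    L_T2: float = np.nan
    x_front1: float = np.nan
    x_rear1: float = np.nan
    x_front2: float = np.nan
    x_rear2: float = np.nan
    height: float = np.nan
    top_area_whole: float = np.nan
    top_area_bulky: float = np.nan
    volume_estimate: float = np.nan
    a_max: float = np.nan
    alpha_a: float = np.nan

    FIELDS = ("theta_f1", "theta_r1", "theta_f2", "theta_r2",
              "L_s1", "L_s2", "L_T1", "L_T2",
              "x_front1", "x_rear1", "x_front2", "x_rear2",
              "height", "top_area_whole", "top_area_bulky",
              "volume_estimate", "a_max", "alpha_a")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.FIELDS}


# ---------------------------------------------------------------------------
# ellipse fitting
# ---------------------------------------------------------------------------

def fit_ellipse(contour: np.ndarray) -> EllipseFit:
    """Direct least-squares ellipse fit to an (N, 2) point set in mm.

    Exact on noiseless conic samples; raises on fewer than 6 points, on
    (near-)collinear input and when no ellipse can be fitted.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("contour must be an (N, 2) array")
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 6:
        raise ValueError("need at least 6 distinct points for an ellipse fit")
    centered = uniq - uniq.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-30):
        raise ValueError("points are collinear; no ellipse fit possible")

    model = EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError("ellipse fit failed (degenerate or non-elliptic input)")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise ValueError("ellipse fit failed (degenerate or non-elliptic input)")
    if a <= 0 or b <= 0:
        raise ValueError("ellipse fit returned non-positive axes")
    phi = np.rad2deg(theta)
    if b > a:
        a, b = b, a
        phi += 90.0
    phi = (phi + 90.0) % 180.0 - 90.0
    if phi <= -90.0:
        phi += 180.0
    return EllipseFit(center=(float(xc), float(yc)), a=float(a), b=float(b),
                      phi_deg=float(phi))


def projected_length(obj: Union[EllipseFit, np.ndarray]) -> float:
    """Extent of the shape's projection onto the x axis, mm.

    Closed form ``2 sqrt(a^2 cos^2 phi + b^2 sin^2 phi)`` for an ellipse;
    ``max x - min x`` for a contour.
    """
    if isinstance(obj, EllipseFit):
        phi = np.deg2rad(obj.phi_deg)
        return float(2.0 * np.sqrt((obj.a * np.cos(phi)) ** 2
                                   + (obj.b * np.sin(phi)) ** 2))
    pts = np.asarray(obj, dtype=float)
    return float(pts[:, 0].max() - pts[:, 0].min())


# ---------------------------------------------------------------------------
# baselines and contact points
# ---------------------------------------------------------------------------

def auto_baseline(contour: np.ndarray, applies_to: str = "whole",
                  lift: float = 0.0) -> Baseline:
    """Baseline through the two lowest contour extremes (left/right halves).

    ``lift`` (mm) raises the line toward the droplet; on thresholded images
    the contour's lowest points sit half a pixel below the substrate's
    pixel-center row, so pipelines pass ``lift = mm_per_px / 2``.
    """
    pts = np.asarray(contour, dtype=float)
    x_mid = 0.5 * (pts[:, 0].min() + pts[:, 0].max())
    left = pts[pts[:, 0] <= x_mid]
    right = pts[pts[:, 0] > x_mid]
    if len(left) == 0 or len(right) == 0:
        raise ValueError("contour does not span two halves")
    p0 = left[np.argmax(left[:, 1])]   # image y down: lowest = max y
    p1 = right[np.argmax(right[:, 1])]
    return Baseline(p0=(p0[0], p0[1] - lift), p1=(p1[0], p1[1] - lift),
                    applies_to=applies_to)


def _baseline_coords(contour: np.ndarray, baseline: Baseline
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Contour vertices as (station, height) in the baseline frame (mm).

    Heights are measured from the baseline line; stations are the absolute
    projection onto the baseline direction (not relative to an endpoint), so
    edge positions are comparable across frames even when the baseline is
    re-estimated per frame.
    """
    p0, u, n = baseline.frame_vectors()
    pts = np.asarray(contour, dtype=float)
    return pts @ u, (pts - p0) @ n


def find_contact_points(contour: np.ndarray, baseline: Baseline,
                        touch_tol: float = 1e-9) -> tuple[float, float]:
    """Leftmost and rightmost sub-pixel intersections of contour and baseline.

    Returns stations (mm along the baseline direction) of the rear and front
    contact points.  Raises when the contour does not cross or touch the
    baseline.
    """
    s, h = _baseline_coords(contour, baseline)
    stations: list[float] = []
    npts = len(s)
    closed = np.allclose([s[0], h[0]], [s[-1], h[-1]])
    last = npts - 1 if closed else npts
    for i in range(last):
        j = (i + 1) % npts
        hi, hj = h[i], h[j]
        if abs(hi) <= touch_tol:
            stations.append(float(s[i]))
        if (hi > touch_tol and hj < -touch_tol) or (hi < -touch_tol and hj > touch_tol):
            f = hi / (hi - hj)
            stations.append(float(s[i] + f * (s[j] - s[i])))
    if not stations:
        raise ValueError("contour does not intersect the baseline")
    return min(stations), max(stations)


# ---------------------------------------------------------------------------
# contact angles
# ---------------------------------------------------------------------------

def _surface_arc(s: np.ndarray, h: np.ndarray, s_c: float, win: float,
                 closed: bool) -> np.ndarray:
    """Indices of the contour arc climbing the droplet surface from s_c."""
    npts = len(s) - 1 if closed else len(s)
    d2 = (s[:npts] - s_c) ** 2 + h[:npts] ** 2
    i0 = int(np.argmin(d2))

    def walk(step: int) -> list[int]:
        out = []
        i = i0
        for _ in range(npts - 1):
            i = (i + step) % npts
            if abs(s[i] - s_c) > win:
                break
            out.append(i)
        return out

    fwd, bwd = walk(+1), walk(-1)

    def climb(ix: list[int]) -> float:
        if not ix:
            return -np.inf
        return float(np.mean(h[ix[:10]]))

    return np.asarray(fwd if climb(fwd) >= climb(bwd) else bwd, dtype=int)


def _arc_length(ss: np.ndarray, hh: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(ss), np.diff(hh)))])


def _presmooth(ss: np.ndarray, hh: np.ndarray, period: float
               ) -> tuple[np.ndarray, np.ndarray]:
    """Boxcar over one staircase period to cancel pixel-quantization sawtooth."""
    arc = _arc_length(ss, hh)
    spacing = float(np.median(np.diff(arc))) if len(arc) > 1 else period
    n = max(int(round(period / max(spacing, 1e-12))), 1)
    if n <= 1 or n >= len(ss):
        return ss, hh
    k = np.ones(n) / n
    return np.convolve(ss, k, "valid"), np.convolve(hh, k, "valid")


def _tangent_poly(ss: np.ndarray, hh: np.ndarray, degree: int
                  ) -> tuple[float, float]:
    """Tangent (ds, dh) of a parametric polynomial fit, at the height-zero
    crossing of the fitted arc (extrapolated contact point)."""
    arc = _arc_length(ss, hh)
    A = np.vander(arc, degree + 1, increasing=True)
    cs, *_ = np.linalg.lstsq(A, ss, rcond=None)
    ch, *_ = np.linalg.lstsq(A, hh, rcond=None)
    t0 = 0.0
    if degree >= 1:
        roots = [r.real for r in np.roots(ch[::-1]) if abs(r.imag) < 1e-9]
        if roots:
            t0 = min(roots, key=abs)
    ds = np.polyder(np.poly1d(cs[::-1]))(t0)
    dh = np.polyder(np.poly1d(ch[::-1]))(t0)
    return float(ds), float(dh)


def _tangent_circle(ss: np.ndarray, hh: np.ndarray, s_c: float
                    ) -> Optional[tuple[float, float]]:
    """Tangent of an algebraic (Kasa) circle fit at its baseline crossing."""
    A = np.column_stack([ss, hh, np.ones_like(ss)])
    b = ss ** 2 + hh ** 2
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover
        return None
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx ** 2 + cy ** 2
    disc = r2 - cy ** 2
    if disc <= 0:
        return None
    s0 = min((cx - np.sqrt(disc), cx + np.sqrt(disc)), key=lambda v: abs(v - s_c))
    # tangent is perpendicular to the radius at the crossing
    return float(cy), float(s0 - cx)


def contact_angle(contour: np.ndarray, baseline: Baseline, which_edge: str,
                  window: float = ANGLE_WINDOW,
                  px_size: Optional[float] = None) -> float:
    """Apparent contact angle (deg, interior-measured, in [0, 180)).

    The contour arc climbing the droplet surface from the contact point is
    fitted in coordinates where the baseline is horizontal, and the angle is
    the arctangent of the fitted tangent at the (extrapolated) baseline
    crossing.  Two local models are used depending on a rough slope probe
    within ``window`` (a fraction of the region's contact length):

    * shallow edges (< ~40 deg): parametric quadratic in arc length, after a
      boxcar over one pixel-staircase period and with the window widened to
      cover several staircase periods — a discretized shallow edge carries
      its slope information only across many columns;
    * steep edges: a parametric quadratic evaluated at two window sizes with
      Richardson extrapolation (cancelling the leading curvature bias); for
      near-vertical edges (>= ~88 deg) an algebraic circle fit instead,
      which has no curvature bias on cap-like profiles and stays
      single-valued beyond 90 deg.

    ``px_size`` (mm) sets the staircase period; when omitted it is inferred
    from the contour vertex spacing.
    """
    if which_edge not in ("front", "rear"):
        raise ValueError("which_edge must be 'front' or 'rear'")
    s, h = _baseline_coords(contour, baseline)
    s_rear, s_front = find_contact_points(contour, baseline)
    Lc = s_front - s_rear
    win0 = window * Lc
    if win0 >= Lc:
        raise ValueError("window spans both edges; reduce it")
    s_c = s_front if which_edge == "front" else s_rear
    closed = np.allclose([s[0], h[0]], [s[-1], h[-1]])

    def windowed(win: float) -> tuple[np.ndarray, np.ndarray]:
        idx = _surface_arc(s, h, s_c, win, closed)
        idx = idx[h[idx] > 1e-9]
        return s[idx], h[idx]

    ss, hh = windowed(win0)
    if len(ss) < 5:
        raise ValueError("too few contour points inside the tangent window")
    if px_size is None:
        px_size = float(np.median(np.diff(_arc_length(ss, hh))))

    ds, dh = _tangent_poly(ss, hh, 1)
    th_rough = abs(np.degrees(np.arctan2(abs(dh), abs(ds))))
    if th_rough < 42.0:
        period = px_size / max(np.tan(np.deg2rad(max(th_rough, 2.0))), 0.02)
        w_eff = float(np.clip(12.0 * period, win0, 0.45 * Lc))
        ss, hh = windowed(w_eff)
        ss, hh = _presmooth(ss, hh, period)
        if len(ss) < 5:
            raise ValueError("too few contour points inside the tangent window")
        ds, dh = _tangent_poly(ss, hh, 2)
        return _interior_angle(ds, dh, which_edge)

    w_eff = max(win0, min(0.2 * Lc, 120.0 * px_size))
    ss, hh = windowed(w_eff)
    tan = _tangent_circle(ss, hh, s_c)
    if tan is not None:
        circ = _interior_angle(*tan, which_edge)
        if circ >= 88.0:
            return circ
    # Richardson extrapolation over windows w and w/2 cancels the O(w^2)
    # curvature bias of the quadratic tangent on non-circular arcs
    estimates = []
    for w in (w_eff, w_eff / 2.0):
        sw, hw = windowed(w)
        sw, hw = _presmooth(sw, hw, px_size)
        if len(sw) < 5:
            raise ValueError("too few contour points inside the tangent window")
        estimates.append(_interior_angle(*_tangent_poly(sw, hw, 2), which_edge))
    return float((4.0 * estimates[1] - estimates[0]) / 3.0)


def _interior_angle(ds: float, dh: float, which_edge: str) -> float:
    if dh < 0:
        ds, dh = -ds, -dh
    if which_edge == "front":
        ang = np.degrees(np.arctan2(dh, -ds))
    else:
        ang = np.degrees(np.arctan2(dh, ds))
    return float(ang % 180.0)


# ---------------------------------------------------------------------------
# lengths, height, volume
# ---------------------------------------------------------------------------

def side_lengths(result: SegmentationResult,
                 baseline_whole: Optional[Baseline] = None,
                 baseline_bulky: Optional[Baseline] = None
                 ) -> tuple[float, float, float]:
    """(L_s1, L_s2, height): per-region side lengths and droplet height (mm).

    Each region is measured against its own baseline (auto-estimated from
    its contour when not supplied); the height is the maximum perpendicular
    distance of the whole-droplet contour from its baseline.
    """
    bw = baseline_whole or auto_baseline(result.contour_whole, "whole")
    bb = baseline_bulky or auto_baseline(result.contour_bulky, "bulky")
    r1, f1 = find_contact_points(result.contour_whole, bw)
    r2, f2 = find_contact_points(result.contour_bulky, bb)
    _, h = _baseline_coords(result.contour_whole, bw)
    return f1 - r1, f2 - r2, float(h.max())


def _upper_profile(contour: np.ndarray, baseline: Baseline,
                   mono_tol_frac: float = 0.02
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Single-valued height profile h(s) of the contour arc above the baseline."""
    s, h = _baseline_coords(contour, baseline)
    s_rear, s_front = find_contact_points(contour, baseline)
    Lc = s_front - s_rear
    closed = np.allclose([s[0], h[0]], [s[-1], h[-1]])
    npts = len(s) - 1 if closed else len(s)
    above = h[:npts] > 1e-9
    if not above.any():
        return np.array([s_rear, s_front]), np.zeros(2)
    idx = np.nonzero(above)[0]
    # rotate the closed contour so the above-baseline arc is contiguous
    if closed and above[0] and above[npts - 1]:
        start = np.nonzero(~above)[0]
        if len(start):
            k = int(start[-1]) + 1
            order = np.r_[np.arange(k, npts), np.arange(0, k)]
            sel = order[above[order]]
        else:
            sel = idx
    else:
        sel = idx
    ss, hs = s[sel], h[sel]
    if ss[0] > ss[-1]:
        ss, hs = ss[::-1], hs[::-1]
    drift = np.maximum.accumulate(ss) - ss  # backtracking along the arc
    if drift.max() > mono_tol_frac * Lc:
        raise ValueError(
            "height profile is not single-valued above the baseline "
            "(contact angle beyond 90 deg?); consider a spherical-cap fit")
    ss = np.concatenate([[s_rear], ss, [s_front]])
    hs = np.concatenate([[0.0], hs, [0.0]])
    order = np.argsort(ss, kind="stable")
    ss, hs = ss[order], hs[order]
    keep = np.concatenate([[True], np.diff(ss) > 1e-12])
    return ss[keep], hs[keep]


def estimate_volume(contour: np.ndarray, baseline: Baseline,
                    n_samples: int = 2000) -> float:
    """Solid-of-revolution volume estimate in microliters (= mm^3).

    The height profile above the baseline is revolved about the vertical
    axis through the profile's area centroid (axisymmetry assumption); the
    two half-solids are averaged, which is exact for symmetric profiles.
    Labelled an estimator: validated only on synthetic solids of revolution.
    """
    ss, hs = _upper_profile(contour, baseline)
    grid = np.linspace(ss[0], ss[-1], n_samples)
    hg = np.interp(grid, ss, hs)
    area = np.trapezoid(hg, grid)
    if area <= 0:
        return 0.0
    s_cent = np.trapezoid(grid * hg, grid) / area
    return float(np.pi * np.trapezoid(np.abs(grid - s_cent) * hg, grid))


# ---------------------------------------------------------------------------
# per-frame measurement pipeline
# ---------------------------------------------------------------------------

def measure_side(result: SegmentationResult,
                 baseline_whole: Optional[Baseline] = None,
                 baseline_bulky: Optional[Baseline] = None,
                 window: float = ANGLE_WINDOW) -> GeometryMeasurement:
    """All side-view quantities from one segmented frame.

    Auto-estimated baselines are lifted by half a pixel: the sub-pixel
    contour's lowest run lies between the last liquid row and the first
    background row, half a pixel below the substrate's pixel-center line.
    """
    px = result.mm_per_px
    bw = baseline_whole or auto_baseline(result.contour_whole, "whole",
                                         lift=0.5 * px)
    bb = baseline_bulky or auto_baseline(result.contour_bulky, "bulky",
                                         lift=0.5 * px)
    m = GeometryMeasurement()
    m.x_rear1, m.x_front1 = find_contact_points(result.contour_whole, bw)
    m.x_rear2, m.x_front2 = find_contact_points(result.contour_bulky, bb)
    m.L_s1, m.L_s2, m.height = side_lengths(result, bw, bb)
    angle_jobs = (("theta_f1", result.contour_whole, bw, "front"),
                  ("theta_r1", result.contour_whole, bw, "rear"),
                  ("theta_f2", result.contour_bulky, bb, "front"),
                  ("theta_r2", result.contour_bulky, bb, "rear"))
    for name, contour, bl, edge in angle_jobs:
        try:
            setattr(m, name, contact_angle(contour, bl, edge, window, px))
        except ValueError as exc:
            warnings.warn(f"{name} unavailable: {exc}")
    try:
        m.volume_estimate = estimate_volume(result.contour_whole, bw)
    except ValueError as exc:
        warnings.warn(f"volume estimate unavailable: {exc}")
    return m


def measure_top(result: SegmentationResult) -> GeometryMeasurement:
    """All top-view quantities from one segmented frame."""
    m = GeometryMeasurement()
    fit1 = fit_ellipse(result.contour_whole)
    fit2 = fit_ellipse(result.contour_bulky)
    m.L_T1 = projected_length(fit1)
    m.L_T2 = projected_length(fit2)
    m.top_area_whole = fit1.area
    m.top_area_bulky = fit2.area
    m.a_max = fit1.A_max
    m.alpha_a = fit1.alpha_A
    return m


def merge_measurements(side: Optional[GeometryMeasurement],
                       top: Optional[GeometryMeasurement]) -> GeometryMeasurement:
    """Combine side- and top-view measurements of the same instant."""
    out = GeometryMeasurement()
    for src in (side, top):
        if src is None:
            continue
        for k in GeometryMeasurement.FIELDS:
            v = getattr(src, k)
            if np.isfinite(v):
                setattr(out, k, v)
    return out


def major_axis_positions(frame: Frame, thresholds: ThresholdPair,
                         result: Optional[SegmentationResult] = None,
                         pad_mm: float = 1.0) -> tuple[AxisPositions, dict]:
    """Positions 1-5 along the fitted major axis of a top-view frame.

    Samples the intensity and Sobel-gradient profiles along the whole-droplet
    major axis extended by ``pad_mm`` beyond each vertex, then locates the
    ellipse rear crossings (p1, p3), the jagged-contour threshold crossings
    (p2, p4) and the front edge (p5).  Returns the positions and an info
    dict (axis origin/direction in mm, stations, profiles) for mapping
    stations back to image coordinates.
    """
    if result is None:
        result = segment_regions_cached(frame, thresholds)
    fit1 = fit_ellipse(result.contour_whole)
    fit2 = fit_ellipse(result.contour_bulky)
    s = frame.mm_per_px
    H, W = frame.shape
    phi = np.deg2rad(fit1.phi_deg)
    u = np.array([np.cos(phi), np.sin(phi)])
    if u[0] < 0:
        u = -u
    c = np.asarray(fit1.center)
    half = fit1.a + pad_mm
    q0, q1 = c - half * u, c + half * u
    # clip the segment to the image interior
    lims = np.array([(W - 1) * s, (H - 1) * s])
    for q in (q0, q1):
        np.clip(q, [0.0, 0.0], lims, out=q)
    grad = seg.sobel_magnitude(frame)
    prof = seg.line_profile(frame.pixels, tuple(q0 / s), tuple(q1 / s))
    gprof = seg.line_profile(grad, tuple(q0 / s), tuple(q1 / s))
    length = float(np.linalg.norm(q1 - q0))
    stations = np.linspace(0.0, length, len(prof))

    t1 = seg.line_ellipse_intersections(q0, u, fit1.center, fit1.a, fit1.b,
                                        fit1.phi_deg)
    t2 = seg.line_ellipse_intersections(q0, u, fit2.center, fit2.a, fit2.b,
                                        fit2.phi_deg)
    pos = seg.locate_axis_positions(
        stations, prof, gprof, thresholds,
        ellipse_rear_whole=None if t1 is None else float(min(t1)),
        ellipse_rear_bulky=None if t2 is None else float(min(t2)))
    info = {"origin": q0, "direction": u, "stations": stations,
            "profile": prof, "gradient": gprof,
            "fit_whole": fit1, "fit_bulky": fit2}
    return pos, info


def segment_regions_cached(frame: Frame, thresholds: ThresholdPair
                           ) -> SegmentationResult:
    return seg.segment_regions(frame, thresholds)
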