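"""Dual-threshold segmentation and gradient-based edge localization.

The droplet appears as three gray populations — dark bulky body, translucent
tail, bright background — so two intensity thresholds split a frame into the
*bulky region* (pixels at or below ``t_bulky``) and the *whole droplet*
including the tail (pixels at or below ``t_whole``).  Thresholds can be set
manually per frame or selected automatically by exact three-class Otsu
(maximization of the between-class variance over all ordered threshold
pairs).  Contours are extracted at sub-pixel precision by linear
interpolation of the threshold crossing between pixel centers.  Edge
stations along the droplet's major axis (positions 1–5: ellipse rear
crossings, jagged-contour rear crossings, and the unambiguous front edge
where intensity recovers to the background level at the strongest gradient
peak) are read off matched intensity/Sobel-gradient line profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure

from .frames import Frame

#: ITU-R BT.601 luma weights used for RGB -> gray conversion
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: gray-level band around the background mode that counts as "recovered"
BACKGROUND_TOL = 5.0


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class ThresholdPair:
    """Two gray thresholds: ``t_bulky < t_whole``.

    Pixels at or below ``t_bulky`` belong to the dark bulky region; pixels at
    or below ``t_whole`` belong to the whole droplet (body + tail).
    """

    t_bulky: float
    t_whole: float

    def __post_init__(self) -> None:
        if not self.t_bulky < self.t_whole:
            raise ValueError(
                f"t_bulky ({self.t_bulky}) must be below t_whole ({self.t_whole})")


@dataclass
class SegmentationResult:
    """Masks and sub-pixel contours for the two droplet regions (mm)."""

    mask_bulky: np.ndarray
    mask_whole: np.ndarray
    contour_bulky: np.ndarray  # (N, 2) columns x_mm, y_mm, closed
    contour_whole: np.ndarray
    thresholds_used: ThresholdPair
    mm_per_px: float = 1.0


@dataclass
class AxisPositions:
    """Edge stations (mm) along the major axis, rear to front.

    ``p1``/``p3``: rear crossings of the axis with the whole/bulky fitted
    ellipses; ``p2``/``p4``: rear threshold crossings of the jagged contour
    on the intensity profile; ``p5``: front station where the intensity
    recovers to the background band, at the strongest front gradient peak.
    Undefined positions are ``None`` with the reason recorded.
    """

    p1: Optional[float] = None
    p2: Optional[float] = None
    p3: Optional[float] = None
    p4: Optional[float] = None
    p5: Optional[float] = None
    reasons: dict = field(default_factory=dict)

    def as_tuple(self) -> tuple:
        return (self.p1, self.p2, self.p3, self.p4, self.p5)


# ---------------------------------------------------------------------------
# intensity basics
# ---------------------------------------------------------------------------

def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an image to 8-bit single-channel gray.

    3-channel input is combined with the BT.601 luma weights
    (0.299 R + 0.587 G + 0.114 B); already-gray input passes through
    unchanged.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=False)
    if arr.ndim == 3 and arr.shape[2] == 3:
        gray = arr.astype(float) @ np.asarray(LUMA_WEIGHTS)
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    raise ValueError(f"unsupported channel count: shape {arr.shape}")


def intensity_histogram(frame: Frame | np.ndarray, percent: bool = False) -> np.ndarray:
    """256-bin gray-level histogram (counts, or percentages of all pixels)."""
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    hist = np.bincount(pixels.ravel(), minlength=256).astype(float)
    if percent:
        return hist / hist.sum() * 100.0
    return hist


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------

def _otsu_two_thresholds(hist: np.ndarray) -> tuple[int, int]:
    """Exact three-class Otsu: the pair (t1, t2), t1 < t2, maximizing the
    between-class variance with classes [0..t1], (t1..t2], (t2..255].

    All ordered pairs are scored; pairs leaving any class empty are
    excluded.  Ties break toward the smallest (t1, t2) in lexicographic
    order.
    """
    h = np.asarray(hist, dtype=float)
    total = h.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    if np.count_nonzero(h) < 3:
        raise ValueError("degenerate histogram: need at least three distinct "
                         "gray levels for three-class thresholding")
    p = h / total
    idx = np.arange(h.size, dtype=float)
    P = np.cumsum(p)
    M = np.cumsum(p * idx)
    mu_T = M[-1]

    t1 = np.arange(h.size - 2)[:, None]   # rows
    t2 = np.arange(1, h.size - 1)[None, :]  # cols
    w0 = P[t1]
    w1 = P[t2] - P[t1]
    w2 = 1.0 - P[t2]
    m0 = np.divide(M[t1], w0, out=np.zeros_like(w0), where=w0 > 0)
    m1 = np.divide(M[t2] - M[t1], w1, out=np.zeros_like(w1), where=w1 > 0)
    m2 = np.divide(mu_T - M[t2], w2, out=np.zeros_like(w2), where=w2 > 0)
    score = w0 * m0 ** 2 + w1 * m1 ** 2 + w2 * m2 ** 2
    valid = (t2 > t1) & (w0 > 0) & (w1 > 0) & (w2 > 0)
    score = np.where(valid, score, -np.inf)
    if not np.isfinite(score).any():
        raise ValueError("no valid three-class partition of this histogram")
    flat = int(np.argmax(score))
    i, j = np.unravel_index(flat, score.shape)
    return int(t1[i, 0]), int(t2[0, j])


def otsu_threshold(hist: np.ndarray) -> int:
    """Exact two-class Otsu threshold t (classes [0..t], (t..255])."""
    h = np.asarray(hist, dtype=float)
    total = h.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    if np.count_nonzero(h) < 2:
        raise ValueError("degenerate histogram: a single gray level cannot be "
                         "thresholded")
    p = h / total
    idx = np.arange(h.size, dtype=float)
    P = np.cumsum(p)
    M = np.cumsum(p * idx)
    mu_T = M[-1]
    w0, w1 = P, 1.0 - P
    m0 = np.divide(M, w0, out=np.zeros_like(w0), where=w0 > 0)
    m1 = np.divide(mu_T - M, w1, out=np.zeros_like(w1), where=w1 > 0)
    score = w0 * m0 ** 2 + w1 * m1 ** 2
    score = np.where((w0 > 0) & (w1 > 0), score, -np.inf)
    return int(np.argmax(score[:-1]))


def select_thresholds(histogram: np.ndarray, mode: str = "auto",
                      t_bulky: Optional[float] = None,
                      t_whole: Optional[float] = None) -> ThresholdPair:
    """Select the dual thresholds, manually or by exact three-class Otsu.

    ``mode="manual"`` returns the provided pair after an ordering check
    (the faithful per-frame-override mode); ``mode="auto"`` maximizes the
    between-class variance over all ordered threshold pairs.
    """
    if mode == "manual":
        if t_bulky is None or t_whole is None:
            raise ValueError("manual mode requires both t_bulky and t_whole")
        return ThresholdPair(t_bulky=t_bulky, t_whole=t_whole)
    if mode == "auto":
        lo, hi = _otsu_two_thresholds(histogram)
        return ThresholdPair(t_bulky=lo, t_whole=hi)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# region segmentation
# ---------------------------------------------------------------------------

def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = int(np.argmax(counts))
    return labels == keep


def _closed_contours(pixels: np.ndarray, level: float) -> list[np.ndarray]:
    cs = measure.find_contours(pixels.astype(float), level)
    return [c for c in cs if len(c) >= 4 and np.allclose(c[0], c[-1])]


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _region_contour(pixels: np.ndarray, threshold: float, name: str) -> np.ndarray:
    """Largest closed sub-pixel iso-contour at level threshold + 0.5 (rows/cols)."""
    contours = _closed_contours(pixels, threshold + 0.5)
    if not contours:
        raise ValueError(f"no closed contour found for the {name} region")
    return max(contours, key=_polygon_area)


def segment_regions(frame: Frame, thresholds: ThresholdPair) -> SegmentationResult:
    """Threshold a frame into bulky and whole-droplet masks and contours.

    Each mask is the largest connected component at its threshold with holes
    filled; the bulky mask is intersected with the whole mask so the
    inclusion ``mask_bulky ⊆ mask_whole`` holds by construction.  Contours
    are closed sub-pixel polylines in mm.
    """
    px = frame.pixels
    raw_whole = px <= thresholds.t_whole
    raw_bulky = px <= thresholds.t_bulky
    if not raw_whole.any():
        raise ValueError(
            f"whole-droplet region vanished at threshold {thresholds.t_whole}")
    if not raw_bulky.any():
        raise ValueError(
            f"bulky region vanished at threshold {thresholds.t_bulky}")

    mask_whole = ndimage.binary_fill_holes(_largest_component(raw_whole))
    mask_bulky = ndimage.binary_fill_holes(_largest_component(raw_bulky)) & mask_whole
    if not mask_bulky.any():  # pragma: no cover - disjoint components
        raise ValueError("bulky region lies outside the whole-droplet region")

    s = frame.mm_per_px
    c_whole = _region_contour(px, thresholds.t_whole, "whole-droplet")[:, ::-1] * s
    c_bulky = _region_contour(px, thresholds.t_bulky, "bulky")[:, ::-1] * s
    return SegmentationResult(mask_bulky=mask_bulky, mask_whole=mask_whole,
                              contour_bulky=c_bulky, contour_whole=c_whole,
                              thresholds_used=thresholds, mm_per_px=s)


# ---------------------------------------------------------------------------
# gradients and line profiles
# ---------------------------------------------------------------------------

def sobel_magnitude(frame: Frame | np.ndarray) -> np.ndarray:
    """Magnitude of the 3x3 horizontal/vertical Sobel response pair.

    Uses the standard unnormalized kernel, so an ideal vertical step of
    height h yields a peak response of 4h.
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    img = pixels.astype(float)
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def line_profile(image: np.ndarray, p0: tuple[float, float],
                 p1: tuple[float, float]) -> np.ndarray:
    """Bilinearly interpolated intensities along the segment p0 -> p1.

    Endpoints are (x, y) pixel coordinates and must lie inside the image;
    samples are spaced 1 px apart, ceil(distance) + 1 of them.
    """
    img = np.asarray(image, dtype=float)
    H, W = img.shape
    for name, (x, y) in (("p0", p0), ("p1", p1)):
        if not (0 <= x <= W - 1 and 0 <= y <= H - 1):
            raise ValueError(f"endpoint {name}={(x, y)} outside the image")
    dist = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
    n = int(np.ceil(dist)) + 1
    t = np.linspace(0.0, 1.0, n)
    xs = p0[0] + t * (p1[0] - p0[0])
    ys = p0[1] + t * (p1[1] - p0[1])
    return ndimage.map_coordinates(img, [ys, xs], order=1)


# ---------------------------------------------------------------------------
# positions 1-5 along the major axis
# ---------------------------------------------------------------------------

def line_ellipse_intersections(p0: np.ndarray, direction: np.ndarray,
                               center: tuple[float, float], a: float, b: float,
                               phi_deg: float) -> Optional[tuple[float, float]]:
    """Signed stations t where the line p0 + t*direction meets the ellipse."""
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    phi = np.deg2rad(phi_deg)
    R = np.array([[np.cos(phi), np.sin(phi)], [-np.sin(phi), np.cos(phi)]])
    q0 = R @ (np.asarray(p0, dtype=float) - np.asarray(center))
    v = R @ u
    A = (v[0] / a) ** 2 + (v[1] / b) ** 2
    B = 2 * (q0[0] * v[0] / a ** 2 + q0[1] * v[1] / b ** 2)
    C = (q0[0] / a) ** 2 + (q0[1] / b) ** 2 - 1.0
    disc = B * B - 4 * A * C
    if disc < 0:
        return None
    r = np.sqrt(disc)
    return ((-B - r) / (2 * A), (-B + r) / (2 * A))


def _first_crossing_below(stations: np.ndarray, profile: np.ndarray,
                          level: float) -> Optional[float]:
    below = profile <= level
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return float(stations[0])
    # linear interpolation of the crossing between samples i-1 and i
    f = (profile[i - 1] - level) / (profile[i - 1] - profile[i])
    return float(stations[i - 1] + f * (stations[i] - stations[i - 1]))


def locate_axis_positions(stations: np.ndarray, profile: np.ndarray,
                          gradient_profile: np.ndarray,
                          thresholds: ThresholdPair,
                          ellipse_rear_whole: Optional[float] = None,
                          ellipse_rear_bulky: Optional[float] = None,
                          background_gray: Optional[float] = None,
                          background_tol: float = BACKGROUND_TOL) -> AxisPositions:
    """Locate the five edge stations along the major-axis profile.

    ``stations`` are mm positions (rear to front) of the profile samples; the
    sampled segment should extend past both droplet ends so the background
    level is visible at both extremes.  ``ellipse_rear_whole``/``bulky`` are
    the rear intersections of the axis with the fitted ellipses (stations in
    the same coordinate), reported through as p1/p3.
    """
    stations = np.asarray(stations, dtype=float)
    profile = np.asarray(profile, dtype=float)
    grad = np.asarray(gradient_profile, dtype=float)
    reasons: dict[str, str] = {}

    if background_gray is None:
        k = max(3, min(10, len(profile) // 10))
        background_gray = float(max(np.median(profile[:k]), np.median(profile[-k:])))

    p1 = ellipse_rear_whole
    if p1 is None:
        reasons["p1"] = "no whole-droplet ellipse intersection provided"
    p3 = ellipse_rear_bulky
    if p3 is None:
        reasons["p3"] = "no bulky ellipse intersection provided"

    p2 = _first_crossing_below(stations, profile, thresholds.t_whole)
    if p2 is None:
        reasons["p2"] = f"profile never drops below t_whole={thresholds.t_whole}"
    p4 = _first_crossing_below(stations, profile, thresholds.t_bulky)
    if p4 is None:
        reasons["p4"] = f"profile never drops below t_bulky={thresholds.t_bulky}"

    # front edge: last station below the background band, then the strongest
    # gradient peak in its neighbourhood (sub-sample parabolic refinement)
    level = background_gray - background_tol
    dark = profile < level
    if not dark.any():
        p5 = None
        reasons["p5"] = "profile never leaves the background band"
    else:
        j = int(np.nonzero(dark)[0][-1])
        lo, hi = max(j - 5, 0), min(j + 6, len(grad))
        k = lo + int(np.argmax(grad[lo:hi]))
        if 0 < k < len(grad) - 1:
            denom = grad[k - 1] - 2 * grad[k] + grad[k + 1]
            delta = 0.0 if denom == 0 else 0.5 * (grad[k - 1] - grad[k + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        step = stations[1] - stations[0] if len(stations) > 1 else 0.0
        p5 = float(stations[k] + delta * step)

    return AxisPositions(p1=p1, p2=p2, p3=p3, p4=p4, p5=p5, reasons=reasons)
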