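"""Synthetic droplet-image renderer with exact ground truth.

Every downstream measurement (segmentation, contact angles, lengths, event
detection, coverage) is validated against images produced here, because the
experimental videos this kind of analysis is normally applied to are not
published.  The renderer emulates the salient features of a dyed sessile
water droplet on a biofilm-coated substrate under a centrifugal ramp:

* a dark bulky liquid-rich region (gray near 0) at the droplet front,
* a thin translucent tail (intermediate gray) left behind at the pinned rear,
* a near-white background,
* jagged top-view contours around two nested ellipses rotated by a small
  in-plane angle ``alpha_A``,
* scripted leaning / spreading / sliding kinematics during a rotation ramp
  (piecewise linear in rotation speed, not a physical simulation).

Side profiles are constructed analytically: a circular-arc cap when the two
contact angles are equal (exact for the spherical-cap case, valid for angles
above 90 deg), and the minimal-degree (quartic) polynomial satisfying the two
endpoint positions, the two endpoint slopes and the peak height otherwise.
Ground-truth angles and lengths are therefore known by construction.

Rendering is hard-edged and deterministic under a fixed seed: a noiseless
frame contains exactly the three gray tones (body, tail, background).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq, minimize_scalar
from skimage.draw import polygon as draw_polygon

from .frames import Frame

# Default photometry: chosen so body / tail / background form three
# well-separated histogram populations on an 8-bit scale.
DEFAULT_BODY_GRAY = 10
DEFAULT_TAIL_GRAY = 180
DEFAULT_BACKGROUND_GRAY = 230

#: side-view tail thickness in pixels (a thin translucent wedge)
TAIL_THICKNESS_PX = 2.0

NEVER = "never"


# ---------------------------------------------------------------------------
# ground-truth descriptors
# ---------------------------------------------------------------------------

@dataclass
class DropletGeometry:
    """Ground-truth shape of one droplet at one instant.

    Angles are apparent contact angles in degrees, measured through the
    liquid; lengths in mm.  ``contact_length`` is the x-extent of the whole
    droplet (including the tail) as seen from the side; ``bulky_length`` is
    the x-extent of the dark bulky region and is anchored at the droplet
    front (the tail trails behind).  ``rear_pinned_x`` is the fixed station
    of the whole-droplet rear edge, mm from the left image border.
    """

    theta_front: float
    theta_rear: float
    contact_length: float
    bulky_length: float
    max_height: float
    tail_gray: int = DEFAULT_TAIL_GRAY
    body_gray: int = DEFAULT_BODY_GRAY
    alpha_A: float = 0.0
    top_minor_axis: float = 2.0
    rear_pinned_x: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.theta_front < 180:
            raise ValueError("theta_front must lie in (0, 180) degrees")
        if not 0 <= self.theta_rear < 180:
            raise ValueError("theta_rear must lie in [0, 180) degrees")
        if not 0 < self.bulky_length <= self.contact_length + 1e-12:
            raise ValueError("need 0 < bulky_length <= contact_length")
        if not self.max_height > 0:
            raise ValueError("max_height must be positive")
        if not self.body_gray < self.tail_gray:
            raise ValueError("body_gray must be darker than tail_gray")
        if not -90 < self.alpha_A <= 90:
            raise ValueError("alpha_A must lie in (-90, 90] degrees")
        if not self.top_minor_axis > 0:
            raise ValueError("top_minor_axis must be positive")

    # -- convenience constructors -------------------------------------------

    @classmethod
    def spherical_cap(cls, theta: float, contact_length: float, **kw) -> "DropletGeometry":
        """Symmetric circular-arc cap; the height follows from theta and L.

        R = L / (2 sin theta), h = R (1 - cos theta).
        """
        th = np.deg2rad(theta)
        R = contact_length / (2.0 * np.sin(th))
        h = R * (1.0 - np.cos(th))
        kw.setdefault("bulky_length", contact_length)
        return cls(theta_front=theta, theta_rear=theta,
                   contact_length=contact_length, max_height=h, **kw)

    @classmethod
    def tear(cls, theta_front: float, theta_rear: float, contact_length: float,
             **kw) -> "DropletGeometry":
        """Asymmetric tear shape; height set to the natural quartic height.

        The natural height is the peak of the quartic with vanishing leading
        free coefficient, i.e. the least-wiggly profile compatible with the
        endpoint slopes.
        """
        L = contact_length
        tr = np.tan(np.deg2rad(theta_rear))
        tf = np.tan(np.deg2rad(theta_front))
        c0 = tr / L
        c1 = (tf - tr) / L ** 2
        xs = np.linspace(0.0, L, 2001)
        h = float(np.max(xs * (L - xs) * (c0 + c1 * xs)))
        kw.setdefault("bulky_length", contact_length)
        return cls(theta_front=theta_front, theta_rear=theta_rear,
                   contact_length=contact_length, max_height=h, **kw)

    @property
    def x_rear(self) -> float:
        return self.rear_pinned_x

    @property
    def x_front(self) -> float:
        return self.rear_pinned_x + self.contact_length

    @property
    def x_bulky_rear(self) -> float:
        return self.x_front - self.bulky_length


@dataclass
class RenderConfig:
    """Image-formation parameters for the synthetic renderer."""

    image_width_px: int = 1000
    image_height_px: int = 500
    mm_per_px: float = 0.005  # 5 um/px, typical of the 7x-magnified video
    background_gray: int = DEFAULT_BACKGROUND_GRAY
    noise_sigma: float = 2.0  # gray levels; set 0 for a noiseless three-tone image
    jaggedness_amplitude: Optional[float] = None  # mm; None -> 1% of minor axis
    jaggedness_correlation_length: float = 0.3  # mm along the boundary
    seed: int = 0
    baseline_row: Optional[int] = None  # side view; None -> 6 px above bottom

    def __post_init__(self) -> None:
        if not self.mm_per_px > 0:
            raise ValueError("mm_per_px must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.jaggedness_amplitude is not None and self.jaggedness_amplitude < 0:
            raise ValueError("jaggedness_amplitude must be non-negative")


@dataclass
class RampScenario:
    """Scripted kinematics of one rotation-ramp experiment.

    Onsets are rotation speeds in rpm; ``NEVER`` (the string ``"never"``)
    marks an edge that stays pinned for the whole ramp, reproducing the
    permanently pinned whole-droplet rear edge observed on biofilms.
    """

    ramp_rate: float = 1.0       # rpm/s
    max_rs: float = 100.0        # rpm
    fps: float = 10.0
    front_depin_rs: float = 54.0
    rear_depin_rs_bulky: Union[float, str] = NEVER
    rear_depin_rs_whole: Union[float, str] = NEVER
    spread_rate: float = 0.1     # mm per rpm once an edge moves
    runoff_rs: Union[float, str] = NEVER
    lean_onset_rs: float = 30.0  # angles constant below this speed
    theta_adv: float = 67.0      # front angle reached (and clamped) at front depin
    theta_rec: float = 11.0      # rear angle reached (and clamped) at rear depin

    def __post_init__(self) -> None:
        if self.ramp_rate <= 0 or self.fps <= 0 or self.max_rs <= 0:
            raise ValueError("ramp_rate, fps and max_rs must be positive")
        ro = self.runoff_rs
        if ro != NEVER and self.front_depin_rs > float(ro):
            raise ValueError("front_depin_rs must not exceed runoff_rs")
        rb, rw = self.rear_depin_rs_bulky, self.rear_depin_rs_whole
        if rb != NEVER and rw != NEVER and float(rw) < float(rb):
            raise ValueError("whole-droplet rear cannot depin before the bulky rear")


class ScriptFrame(NamedTuple):
    time: float
    rotation_speed: float
    geometry: DropletGeometry


# ---------------------------------------------------------------------------
# side profile construction
# ---------------------------------------------------------------------------

_SYMMETRY_TOL = 1e-9  # degrees


def _arc_params(theta_deg: float, L: float) -> tuple[float, float, float]:
    """Circle (xc, zc, R) of the symmetric cap with chord L on the baseline."""
    th = np.deg2rad(theta_deg)
    R = L / (2.0 * np.sin(th))
    zc = -R * np.cos(th)
    return L / 2.0, zc, R


def _quartic_free_coeff(L: float, tr: float, tf: float, h: float) -> float:
    """Free quartic coefficient c2 such that the profile peak equals h.

    Profile z(x) = x (L - x) (c0 + c1 x + c2 x^2) with c0, c1 fixed by the
    endpoint slopes.  The peak is a convex-like function of c2 with a single
    minimum; of the (up to) two roots of peak(c2) = h, the one closer to zero
    (the least oscillatory profile) is returned.
    """
    c0 = tr / L
    d = (tf - tr) / L
    xs = np.linspace(0.0, L, 4001)

    def peak(c2: float) -> float:
        c1 = (d - c2 * L * L) / L
        return float(np.max(xs * (L - xs) * (c0 + c1 * xs + c2 * xs ** 2)))

    scale = max(h, abs(tr) * L, abs(tf) * L, 1e-9) / L ** 3
    # locate the interior minimum of peak(c2) by expanding-scan, then refine
    span = 10.0 * scale
    for _ in range(60):
        grid = np.linspace(-span, span, 201)
        vals = [peak(c) for c in grid]
        j = int(np.argmin(vals))
        if 0 < j < len(grid) - 1:
            break
        span *= 4.0
    res = minimize_scalar(peak, bounds=(grid[j - 1], grid[j + 1]), method="bounded",
                          options={"xatol": 1e-14})
    c2_min, peak_min = float(res.x), float(res.fun)
    if peak_min > h * (1 + 1e-9):
        raise ValueError(
            f"max_height={h} is unattainable for these contact angles; "
            f"the flattest admissible profile peaks at {peak_min:.4g} mm"
        )
    roots = []
    for sign in (-1.0, 1.0):
        step = sign * max(abs(c2_min), scale)
        lo, hi = c2_min, c2_min + step
        for _ in range(80):
            if peak(hi) >= h:
                break
            step *= 2.0
            hi = c2_min + step
        else:  # pragma: no cover - pathological
            continue
        if sign < 0:
            lo, hi = hi, lo
        roots.append(brentq(lambda c: peak(c) - h, lo, hi, xtol=1e-14))
    if not roots:  # pragma: no cover
        raise RuntimeError("quartic height matching failed")
    return min(roots, key=abs)


def _quartic_coeffs(geometry: DropletGeometry) -> tuple[float, float, float]:
    L = geometry.contact_length
    tr = np.tan(np.deg2rad(geometry.theta_rear))
    tf = np.tan(np.deg2rad(geometry.theta_front))
    c2 = _quartic_free_coeff(L, tr, tf, geometry.max_height)
    c0 = tr / L
    c1 = ((tf - tr) / L - c2 * L * L) / L
    return c0, c1, c2


def _is_symmetric(geometry: DropletGeometry) -> bool:
    return abs(geometry.theta_front - geometry.theta_rear) <= _SYMMETRY_TOL


def _uses_arc(geometry: DropletGeometry) -> bool:
    """Arc construction for symmetric caps; quartic otherwise (angles < 90)."""
    if _is_symmetric(geometry):
        return True
    if max(geometry.theta_front, geometry.theta_rear) >= 90.0:
        raise ValueError(
            "an asymmetric profile with a contact angle >= 90 deg would be "
            "multivalued; only the symmetric circular-arc construction "
            "supports angles >= 90 deg"
        )
    return False


def make_side_profile(geometry: DropletGeometry, n_points: int = 1001) -> np.ndarray:
    """Ordered (x, z) contour of the whole-droplet side profile, in mm.

    Points run from the rear contact point ``(x_rear, 0)`` over the apex to
    the front contact point ``(x_front, 0)``.  For symmetric caps the profile
    is a circular arc (exact spherical-cap section, valid for any angle in
    (0, 180)); otherwise it is the quartic polynomial with the prescribed
    endpoint slopes (tan(theta_rear) at the rear, -tan(theta_front) at the
    front, measured through the liquid) and peak height, clipped at zero.
    """
    L = geometry.contact_length
    x0 = geometry.rear_pinned_x
    if _uses_arc(geometry):
        xc, zc, R = _arc_params(geometry.theta_front, L)
        h_arc = zc + R
        if abs(h_arc - geometry.max_height) > max(1e-3, 1e-6 * R):
            raise ValueError(
                f"max_height={geometry.max_height} inconsistent with the "
                f"circular-arc cap height {h_arc:.6g} mm implied by "
                f"theta={geometry.theta_front} deg and L={L} mm; "
                "use DropletGeometry.spherical_cap()"
            )
        th = np.deg2rad(geometry.theta_front)
        # polar angle from the circle centre: rear contact at pi/2 + th,
        # front contact at pi/2 - th (z >= 0 throughout)
        ang = np.linspace(np.pi / 2 + th, np.pi / 2 - th, n_points)
        xs = xc + R * np.cos(ang)
        zs = zc + R * np.sin(ang)
    else:
        c0, c1, c2 = _quartic_coeffs(geometry)
        xs = np.linspace(0.0, L, n_points)
        zs = np.clip(xs * (L - xs) * (c0 + c1 * xs + c2 * xs ** 2), 0.0, None)
    return np.column_stack([xs + x0, zs])


def _profile_height(geometry: DropletGeometry, x_mm: np.ndarray) -> np.ndarray:
    """Single-valued height z(x) in mm at absolute stations x (angles < 90)."""
    x = np.asarray(x_mm, dtype=float) - geometry.rear_pinned_x
    L = geometry.contact_length
    inside = (x >= 0) & (x <= L)
    z = np.zeros_like(x)
    if _is_symmetric(geometry) and geometry.theta_front <= 90.0 + 1e-12:
        xc, zc, R = _arc_params(geometry.theta_front, L)
        arg = np.clip(R ** 2 - (x - xc) ** 2, 0.0, None)
        z = np.where(inside, zc + np.sqrt(arg), 0.0)
    elif _is_symmetric(geometry):
        raise ValueError("height profile is multivalued for angles > 90 deg")
    else:
        c0, c1, c2 = _quartic_coeffs(geometry)
        z = np.where(inside, x * (L - x) * (c0 + c1 * x + c2 * x ** 2), 0.0)
    return np.clip(z, 0.0, None)


# ---------------------------------------------------------------------------
# side-view rendering
# ---------------------------------------------------------------------------

def _check_fit(geometry: DropletGeometry, config: RenderConfig,
               baseline_row: int) -> None:
    s = config.mm_per_px
    w_mm = config.image_width_px * s
    if geometry.x_rear < 0:
        raise ValueError("profile out of frame: rear edge past the left border")
    if geometry.x_front > w_mm:
        raise ValueError("profile out of frame: front edge past the right border")
    if geometry.max_height > baseline_row * s:
        raise ValueError("profile out of frame: apex above the top border")


def render_side_view(geometry: DropletGeometry, config: RenderConfig,
                     *, time: float = 0.0, rotation_speed: float = 0.0) -> Frame:
    """Render the side (x–z) view as an 8-bit grayscale frame.

    Pixels inside the dark bulky region take ``body_gray``; the tail — the
    span between the pinned rear edge and the bulky rear edge — is drawn as a
    thin translucent wedge (at most ~2 px tall) at ``tail_gray``; everything
    else is ``background_gray``.  Seeded Gaussian noise is added when
    ``noise_sigma > 0``.  The substrate baseline row is recorded in the frame
    metadata and as the frame's ``baseline``.
    """
    H, W = config.image_height_px, config.image_width_px
    s = config.mm_per_px
    brow = config.baseline_row if config.baseline_row is not None else H - 6
    if not 0 < brow < H:
        raise ValueError("baseline_row outside the image")
    _check_fit(geometry, config, brow)

    cols = np.arange(W)
    rows = np.arange(H)
    x_mm = cols * s
    z_mm = (brow - rows) * s  # z up, zero on the baseline row

    img = np.full((H, W), float(config.background_gray))
    steep = _is_symmetric(geometry) and geometry.theta_front > 90.0 + 1e-12
    if steep:
        if geometry.bulky_length < geometry.contact_length - 1e-12:
            raise ValueError("tail rendering requires contact angles < 90 deg")
        xc, zc, R = _arc_params(geometry.theta_front, geometry.contact_length)
        xc += geometry.rear_pinned_x
        X, Z = np.meshgrid(x_mm, z_mm)
        body = ((X - xc) ** 2 + (Z - zc) ** 2 <= R ** 2) & (Z >= 0)
        img[body] = geometry.body_gray
    else:
        z_prof = _profile_height(geometry, x_mm)  # per column
        Z = z_mm[:, None]
        under = (Z >= 0) & (Z <= z_prof[None, :]) & (z_prof[None, :] > 0)
        bulky_cols = x_mm >= geometry.x_bulky_rear - 1e-12
        tail_cap = TAIL_THICKNESS_PX * s
        tail = under & ~bulky_cols[None, :] & (Z <= tail_cap)
        body = under & bulky_cols[None, :]
        img[tail] = geometry.tail_gray
        img[body] = geometry.body_gray

    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        img = img + rng.normal(0.0, config.noise_sigma, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    baseline = ((0.0, float(brow)), (float(W - 1), float(brow)))
    return Frame(pixels=pixels, time=time, rotation_speed=rotation_speed,
                 view="side", mm_per_px=s, baseline=baseline,
                 meta={"baseline_row": brow, "geometry": geometry})


# ---------------------------------------------------------------------------
# top-view rendering
# ---------------------------------------------------------------------------

def _jagged_boundary(center: tuple[float, float], a: float, b: float,
                     phi_deg: float, amplitude: float, corr_len: float,
                     rng: np.random.Generator, n_points: int = 720) -> np.ndarray:
    """Ellipse boundary with smooth correlated radial perturbation (mm).

    The perturbation is a mean-zero periodic Gaussian random function of the
    ellipse parameter, synthesized from Fourier modes with a Gaussian
    spectral decay set by the correlation length along the boundary, and
    normalized to the requested RMS amplitude.  Applied along the outward
    normal.
    """
    t = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    ct, st = np.cos(t), np.sin(t)
    phi = np.deg2rad(phi_deg)
    R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    pts = (R @ np.vstack([a * ct, b * st])).T + np.asarray(center)
    # outward normal of the ellipse at parameter t (before rotation):
    nrm = np.vstack([b * ct, a * st])
    nrm = (R @ nrm).T
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)

    if amplitude > 0:
        perimeter = float(np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b))))
        kmax = 64
        k = np.arange(1, kmax + 1)
        decay = np.exp(-0.5 * (2 * np.pi * k * corr_len / perimeter) ** 2)
        ak = rng.normal(size=kmax) * decay
        bk = rng.normal(size=kmax) * decay
        noise = ak @ np.cos(np.outer(k, t)) + bk @ np.sin(np.outer(k, t))
        rms = np.sqrt(np.mean(noise ** 2))
        if rms > 0:
            noise *= amplitude / rms
        pts = pts + noise[:, None] * nrm
    return pts


def _ellipse_semi_major(x_extent: float, b: float, phi_deg: float) -> float:
    """Semi-major axis giving the requested x-projection at orientation phi."""
    phi = np.deg2rad(phi_deg)
    half = x_extent / 2.0
    val = half ** 2 - (b * np.sin(phi)) ** 2
    if val <= 0 or abs(np.cos(phi)) < 1e-12:
        raise ValueError("alpha_A too large for the requested x-extent")
    a = np.sqrt(val) / abs(np.cos(phi))
    if a < b:
        raise ValueError("top_minor_axis exceeds the achievable major axis")
    return float(a)


def _fill_polygon(poly_mm: np.ndarray, shape: tuple[int, int], s: float) -> np.ndarray:
    rr, cc = draw_polygon(poly_mm[:, 1] / s, poly_mm[:, 0] / s, shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def render_top_view(geometry: DropletGeometry, config: RenderConfig,
                    *, time: float = 0.0, rotation_speed: float = 0.0
                    ) -> tuple[Frame, dict]:
    """Render the top (x–y) view and return it with the exact ground truth.

    Ground truth is a pair of nested ellipses — whole droplet and dark bulky
    region — rotated by ``alpha_A`` and sharing their front vertex along the
    major axis, with a seeded smooth radial perturbation (the jagged contour)
    applied to each boundary.  Interior gray is ``body_gray`` inside the
    bulky contour, ``tail_gray`` in the annular tail, background elsewhere.
    Tail pixels are clipped so that none lies forward (larger x) of the bulky
    region's front.

    Returns
    -------
    (frame, truth)
        ``truth`` holds, per region, the exact ellipse parameters
        (center mm, semi-axes mm, orientation deg) and the jagged polygon.
    """
    H, W = config.image_height_px, config.image_width_px
    s = config.mm_per_px
    phi = geometry.alpha_A
    b1 = geometry.top_minor_axis / 2.0
    a1 = _ellipse_semi_major(geometry.contact_length, b1, phi)
    b2 = b1 * geometry.bulky_length / geometry.contact_length
    a2 = (a1 * geometry.bulky_length / geometry.contact_length
          if geometry.bulky_length < geometry.contact_length else a1)

    cy = H * s / 2.0
    cx1 = (geometry.x_rear + geometry.x_front) / 2.0
    c1 = (cx1, cy)
    # bulky ellipse shares the front vertex of the major axis
    u = np.array([np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))])
    c2 = tuple(np.asarray(c1) + (a1 - a2) * u)

    amp = (config.jaggedness_amplitude if config.jaggedness_amplitude is not None
           else 0.01 * geometry.top_minor_axis)
    rng = np.random.default_rng(config.seed)
    rng_whole, rng_bulky = rng.spawn(2)
    poly_whole = _jagged_boundary(c1, a1, b1, phi, amp,
                                  config.jaggedness_correlation_length, rng_whole)
    poly_bulky = _jagged_boundary(c2, a2, b2, phi, amp,
                                  config.jaggedness_correlation_length, rng_bulky)

    for poly, name in ((poly_whole, "whole"), (poly_bulky, "bulky")):
        if poly[:, 0].min() < 0:
            raise ValueError(f"{name} contour out of frame: past the left border")
        if poly[:, 0].max() > W * s:
            raise ValueError(f"{name} contour out of frame: past the right border")
        if poly[:, 1].min() < 0 or poly[:, 1].max() > H * s:
            raise ValueError(f"{name} contour out of frame: past the top/bottom border")

    mask_whole = _fill_polygon(poly_whole, (H, W), s)
    mask_bulky = _fill_polygon(poly_bulky, (H, W), s) & mask_whole
    if geometry.bulky_length >= geometry.contact_length:
        mask_bulky = mask_whole.copy()
    # no tail pixel forward of the bulky front
    if mask_bulky.any():
        front_col = int(np.max(np.nonzero(mask_bulky.any(axis=0))[0]))
        tail = mask_whole & ~mask_bulky
        tail[:, front_col + 1:] = False
        mask_whole = mask_bulky | tail
    else:  # pragma: no cover - degenerate
        tail = mask_whole & ~mask_bulky

    img = np.full((H, W), float(config.background_gray))
    img[mask_whole] = geometry.tail_gray
    img[mask_bulky] = geometry.body_gray
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = {
        "whole": {"center": c1, "a": a1, "b": b1, "phi_deg": phi,
                  "polygon": poly_whole},
        "bulky": {"center": tuple(c2), "a": a2, "b": b2, "phi_deg": phi,
                  "polygon": poly_bulky},
        "A_max": 2 * a1,
        "alpha_A": phi,
        "jaggedness_amplitude": amp,
    }
    frame = Frame(pixels=pixels, time=time, rotation_speed=rotation_speed,
                  view="top", mm_per_px=s, meta={"truth": truth,
                                                 "geometry": geometry})
    return frame, truth


# ---------------------------------------------------------------------------
# scripted ramp kinematics
# ---------------------------------------------------------------------------

def _onset(value: Union[float, str]) -> Optional[float]:
    return None if value == NEVER else float(value)


def script_ramp(scenario: RampScenario, initial: DropletGeometry
                ) -> tuple[list[ScriptFrame], dict]:
    """Generate the frame-wise ground-truth geometry of a rotation ramp.

    Piecewise-linear kinematics in rotation speed (RS):

    * below ``lean_onset_rs`` both angles hold their initial values;
    * between leaning onset and the respective depinning onsets the front
      angle rises linearly to ``theta_adv`` and the rear angle falls linearly
      to ``theta_rec``, with all edges pinned;
    * at ``front_depin_rs`` the front edge starts advancing at
      ``spread_rate`` mm/rpm and the front angle clamps at its onset value;
    * the bulky rear edge starts advancing at ``rear_depin_rs_bulky`` (a tail
      then stops growing); the whole-droplet rear edge stays at
      ``rear_pinned_x`` forever when ``rear_depin_rs_whole`` is ``"never"``.

    Returns the list of ``(time, rotation_speed, geometry)`` frames and a
    ground-truth event table (onsets, onset angles, per-frame regime labels).
    """
    dt = 1.0 / scenario.fps
    t_end = scenario.max_rs / scenario.ramp_rate
    n_frames = int(np.floor(t_end / dt)) + 1

    f_on = scenario.front_depin_rs
    rb_on = _onset(scenario.rear_depin_rs_bulky)
    rw_on = _onset(scenario.rear_depin_rs_whole)
    ro_on = _onset(scenario.runoff_rs)
    lean_on = scenario.lean_onset_rs

    th_f0, th_r0 = initial.theta_front, initial.theta_rear
    rear_target_rs = rb_on if rb_on is not None else (
        rw_on if rw_on is not None else scenario.max_rs)

    x_front0 = initial.x_front
    x_bulky_rear0 = initial.x_bulky_rear

    frames: list[ScriptFrame] = []
    regimes: list[str] = []
    for i in range(n_frames):
        t = i * dt
        rs = min(scenario.ramp_rate * t, scenario.max_rs)

        # angles (linear in RS between leaning onset and depinning onsets)
        if rs <= lean_on:
            th_f, th_r = th_f0, th_r0
        else:
            span_f = max(f_on - lean_on, 1e-9)
            frac_f = min((rs - lean_on) / span_f, 1.0)
            th_f = th_f0 + (scenario.theta_adv - th_f0) * frac_f
            span_r = max(rear_target_rs - lean_on, 1e-9)
            frac_r = min((rs - lean_on) / span_r, 1.0)
            th_r = th_r0 + (scenario.theta_rec - th_r0) * frac_r
        th_r = max(th_r, 0.5)

        # edges
        x_front = x_front0 + (scenario.spread_rate * (rs - f_on) if rs >= f_on else 0.0)
        if rb_on is not None and rs >= rb_on:
            x_bulky_rear = x_bulky_rear0 + scenario.spread_rate * (rs - rb_on)
        else:
            x_bulky_rear = x_bulky_rear0
        if rw_on is not None and rs >= rw_on:
            x_rear = initial.rear_pinned_x + scenario.spread_rate * (rs - rw_on)
        else:
            x_rear = initial.rear_pinned_x
        x_bulky_rear = min(max(x_bulky_rear, x_rear), x_front - 1e-9)

        geom = dataclasses.replace(
            initial,
            theta_front=th_f, theta_rear=th_r,
            contact_length=x_front - x_rear,
            bulky_length=x_front - x_bulky_rear,
            rear_pinned_x=x_rear,
        )
        frames.append(ScriptFrame(time=t, rotation_speed=rs, geometry=geom))

        if ro_on is not None and rs >= ro_on:
            regimes.append("runoff")
        elif rw_on is not None and rs >= rw_on:
            regimes.append("sliding")
        elif rs >= f_on:
            regimes.append("spreading")
        elif rs > lean_on:
            regimes.append("leaning")
        else:
            regimes.append("static")

    events = {
        "front_depin_rs": f_on,
        "rear_depin_rs_bulky": rb_on,
        "rear_depin_rs_whole": rw_on,
        "runoff_rs": ro_on,
        "lean_onset_rs": lean_on,
        "theta_adv": scenario.theta_adv,
        "theta_rec": scenario.theta_rec,
        "regimes": regimes,
    }
    return frames, events


# ---------------------------------------------------------------------------
# coverage fixtures
# ---------------------------------------------------------------------------

def render_coverage_image(target_fraction: float, blob_count: int = 40,
                          blob_scale: float = 8.0,
                          config: Optional[RenderConfig] = None,
                          *, covered_gray: int = 60, background_gray: int = 200
                          ) -> tuple[Frame, float]:
    """Synthetic stained-micrograph stand-in with a known covered fraction.

    Dark patchy clusters on a light background, emulating crystal-violet
    stained biofilm patches.  A smooth random field (``blob_count`` seeded
    Gaussian bumps of scale ``blob_scale`` px) is thresholded at the quantile
    that realizes ``target_fraction``; the returned ``true_fraction`` is the
    exact dark-pixel fraction and differs from the target by at most the
    quantization of one pixel (well under 1%).
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    config = config or RenderConfig(image_width_px=512, image_height_px=512)
    H, W = config.image_height_px, config.image_width_px
    rng = np.random.default_rng(config.seed)

    if target_fraction <= 0.0:
        mask = np.zeros((H, W), dtype=bool)
    elif target_fraction >= 1.0:
        mask = np.ones((H, W), dtype=bool)
    else:
        field = np.zeros((H, W))
        r = rng.integers(0, H, blob_count)
        c = rng.integers(0, W, blob_count)
        amp = rng.uniform(0.5, 1.5, blob_count)
        np.add.at(field, (r, c), amp)
        field = ndimage.gaussian_filter(field, blob_scale, mode="wrap")
        field += 1e-9 * rng.standard_normal(field.shape)  # break ties
        cut = np.quantile(field, 1.0 - target_fraction)
        mask = field >= cut

    true_fraction = float(mask.mean())
    img = np.full((H, W), float(background_gray))
    img[mask] = covered_gray
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    frame = Frame(pixels=pixels, view="top", mm_per_px=config.mm_per_px,
                  meta={"true_fraction": true_fraction})
    return frame, true_fraction
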