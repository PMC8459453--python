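"""Shared fixtures: rendered reference droplets reused across test modules."""

import numpy as np
import pytest

import dropwet as dw

#: manual thresholds sitting mid-gap between the default render grays
#: (body 10 / tail 180 / background 230)
MANUAL_THRESHOLDS = dw.ThresholdPair(t_bulky=95, t_whole=205)


def side_config(**kw) -> dw.RenderConfig:
    base = dict(image_width_px=900, image_height_px=520, mm_per_px=0.005,
                noise_sigma=0.0, seed=0)
    base.update(kw)
    return dw.RenderConfig(**base)


def top_config(**kw) -> dw.RenderConfig:
    base = dict(image_width_px=1300, image_height_px=900, mm_per_px=0.005,
                noise_sigma=0.0, seed=0)
    base.update(kw)
    return dw.RenderConfig(**base)


@pytest.fixture(scope="session")
def cap67_side():
    """Noiseless side view of a symmetric 67-degree spherical cap, L = 3 mm."""
    geom = dw.DropletGeometry.spherical_cap(67, 3.0, rear_pinned_x=0.7)
    frame = dw.render_side_view(geom, side_config())
    return geom, frame


@pytest.fixture(scope="session")
def tear_side():
    """Noiseless side view of an asymmetric tear (front 40, rear 11 deg)."""
    geom = dw.DropletGeometry.tear(40, 11, 3.0, rear_pinned_x=0.7)
    frame = dw.render_side_view(geom, side_config())
    return geom, frame


@pytest.fixture(scope="session")
def tailed_side():
    """Noiseless side view with a thin translucent tail behind the bulky body."""
    geom = dw.DropletGeometry.tear(40, 11, 5.0, bulky_length=3.0,
                                   rear_pinned_x=0.5)
    frame = dw.render_side_view(geom, side_config(image_width_px=1300))
    return geom, frame


@pytest.fixture(scope="session")
def smooth_top():
    """Noiseless, jaggedness-free top view (exact nested ellipses)."""
    geom = dw.DropletGeometry(theta_front=67, theta_rear=30, contact_length=4.0,
                              bulky_length=3.0, max_height=1.0, alpha_A=4.0,
                              top_minor_axis=2.4, rear_pinned_x=1.0)
    frame, truth = dw.render_top_view(geom, top_config(jaggedness_amplitude=0.0))
    return geom, frame, truth


@pytest.fixture(scope="session")
def jagged_top():
    """Noiseless top view at the default jaggedness (1% of the minor axis)."""
    geom = dw.DropletGeometry(theta_front=67, theta_rear=30, contact_length=4.0,
                              bulky_length=3.0, max_height=1.0, alpha_A=4.0,
                              top_minor_axis=2.4, rear_pinned_x=1.0)
    frame, truth = dw.render_top_view(geom, top_config(seed=7))
    return geom, frame, truth


def three_class_score(hist: np.ndarray, t1: int, t2: int) -> float:
    """Between-class variance objective of the partition [0,t1],(t1,t2],(t2,255]."""
    p = hist / hist.sum()
    idx = np.arange(256)
    score = 0.0
    for lo, hi in ((0, t1 + 1), (t1 + 1, t2 + 1), (t2 + 1, 256)):
        w = p[lo:hi].sum()
        if w <= 0:
            return -np.inf
        m = (p[lo:hi] * idx[lo:hi]).sum() / w
        score += w * m * m
    return float(score)


def brute_force_two_thresholds(hist: np.ndarray) -> tuple[int, int]:
    """Exhaustive-search oracle for the three-class between-class variance."""
    p = hist / hist.sum()
    idx = np.arange(256)
    mu = float((p * idx).sum())
    best, arg = -np.inf, None
    for t1 in range(255):
        for t2 in range(t1 + 1, 255):
            score = 0.0
            ok = True
            for lo, hi in ((0, t1 + 1), (t1 + 1, t2 + 1), (t2 + 1, 256)):
                w = p[lo:hi].sum()
                if w <= 0:
                    ok = False
                    break
                m = (p[lo:hi] * idx[lo:hi]).sum() / w
                score += w * m * m
            if ok and score > best:
                best, arg = score, (t1, t2)
    return arg


def two_class_score(hist: np.ndarray, t: int) -> float:
    """Between-class variance objective of the partition [0,t],(t,255]."""
    p = hist / hist.sum()
    idx = np.arange(256)
    w0 = p[:t + 1].sum()
    w1 = 1.0 - w0
    if w0 <= 0 or w1 <= 0:
        return -np.inf
    m0 = (p[:t + 1] * idx[:t + 1]).sum() / w0
    m1 = (p[t + 1:] * idx[t + 1:]).sum() / w1
    return float(w0 * m0 * m0 + w1 * m1 * m1)


def brute_force_threshold(hist: np.ndarray) -> int:
    """Exhaustive-search oracle for the two-class between-class variance."""
    p = hist / hist.sum()
    idx = np.arange(256)
    best, arg = -np.inf, None
    for t in range(255):
        w0 = p[:t + 1].sum()
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            continue
        m0 = (p[:t + 1] * idx[:t + 1]).sum() / w0
        m1 = (p[t + 1:] * idx[t + 1:]).sum() / w1
        score = w0 * m0 * m0 + w1 * m1 * m1
        if score > best:
            best, arg = score, t
    return arg
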