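"""Calibrated grayscale frames and frame sequences.

A :class:`Frame` is one 8-bit grayscale image together with its acquisition
metadata: elapsed time, the rotation speed of the centrifugal stage at that
instant, the camera view (``"side"`` for the x–z plane, ``"top"`` for the
x–y plane) and the pixel-to-millimetre calibration for that view.  The image
x axis points in the centrifugal (droplet-motion) direction; the origin is
the top-left pixel and coordinates refer to 0-based pixel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Optional, Sequence

import numpy as np

VIEWS = ("side", "top")


@dataclass
class Calibration:
    """Per-view pixel size.  Side and top cameras are calibrated independently."""

    view: str
    mm_per_px: float

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if not self.mm_per_px > 0:
            raise ValueError("mm_per_px must be positive")


@dataclass
class Frame:
    """One calibrated 8-bit grayscale image.

    Parameters
    ----------
    pixels
        2-D uint8 array, gray 0 (black) to 255 (white).
    time
        Elapsed time since the start of the ramp, s.
    rotation_speed
        Stage rotation speed at acquisition, rpm.
    view
        ``"side"`` (x–z plane) or ``"top"`` (x–y plane).
    mm_per_px
        Calibration for this view, mm per pixel.
    baseline
        Optional substrate line for side views, two ``(x, y)`` endpoints in
        pixel coordinates.
    meta
        Free-form metadata (e.g. renderer ground truth).
    """

    pixels: np.ndarray
    time: float = 0.0
    rotation_speed: float = 0.0
    view: str = "side"
    mm_per_px: float = 1.0
    baseline: Optional[tuple[tuple[float, float], tuple[float, float]]] = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be a 2-D array, got ndim={px.ndim}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if not self.mm_per_px > 0:
            raise ValueError("mm_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def baseline_mm(self) -> Optional[tuple[tuple[float, float], tuple[float, float]]]:
        """Baseline endpoints converted to mm, or None when absent."""
        if self.baseline is None:
            return None
        (x0, y0), (x1, y1) = self.baseline
        s = self.mm_per_px
        return ((x0 * s, y0 * s), (x1 * s, y1 * s))


class FrameSeries(Sequence):
    """An ordered sequence of frames from a single view."""

    def __init__(self, frames: Sequence[Frame]):
        frames = list(frames)
        if frames:
            views = {f.view for f in frames}
            if len(views) > 1:
                raise ValueError(f"mixed views in one series: {sorted(views)}")
        self._frames = frames

    def __len__(self) -> int:
        return len(self._frames)

    def __getitem__(self, i):  # type: ignore[override]
        if isinstance(i, slice):
            return FrameSeries(self._frames[i])
        return self._frames[i]

    def __iter__(self) -> Iterator[Frame]:
        return iter(self._frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self._frames])

    @property
    def rotation_speeds(self) -> np.ndarray:
        return np.array([f.rotation_speed for f in self._frames])
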