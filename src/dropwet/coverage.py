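"""Biofilm surface-coverage quantification from stained micrographs.

Crystal-violet staining darkens biofilm-covered regions, so coverage is the
fraction of sufficiently dark pixels after mild smoothing: each image is
mean-filtered to suppress illumination nonuniformity, thresholded (manually
or by exact two-class Otsu), and the covered area is reported as a
percentage of the image.  Replicates are summarized by their sample mean and
standard deviation (n-1 denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .frames import Frame
from .segmentation import intensity_histogram, otsu_threshold

#: default mean-filter kernel size, px
SMOOTH_KERNEL = 5


@dataclass
class CoverageResult:
    """Coverage summary over one or more images (percent of image area)."""

    covered_fraction: float          # mean covered %, same as mean_pct
    threshold_used: Optional[float]
    n_images: int
    mean_pct: float
    sd_pct: float                    # NaN for a single image
    per_image_pct: tuple = ()

    def __post_init__(self) -> None:
        if not 0 <= self.covered_fraction <= 100:
            raise ValueError("covered_fraction must lie in [0, 100]")
        if not (math.isnan(self.sd_pct) or self.sd_pct >= 0):
            raise ValueError("sd_pct must be non-negative")


def smooth_image(frame: Union[Frame, np.ndarray], kernel_size: int = SMOOTH_KERNEL
                 ) -> np.ndarray:
    """Mean filter of odd size; size 1 is the identity.  Returns float array."""
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be an odd integer >= 1")
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    img = pixels.astype(float)
    if kernel_size == 1:
        return img
    return ndimage.uniform_filter(img, size=kernel_size, mode="reflect")


def segment_coverage(frame: Union[Frame, np.ndarray],
                     threshold: Union[str, float] = "auto",
                     stain_darkens: bool = True,
                     kernel_size: int = SMOOTH_KERNEL
                     ) -> tuple[np.ndarray, float]:
    """Binary covered-area mask of one stained micrograph.

    Smooths with a mean filter, then marks stained pixels: at or below the
    threshold when ``stain_darkens`` (the crystal-violet convention), above
    it otherwise.  ``threshold="auto"`` uses the exact two-class Otsu
    threshold of the smoothed image.  Returns (mask, threshold_used).
    """
    img = smooth_image(frame, kernel_size)
    quantized = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if threshold == "auto":
        t = float(otsu_threshold(intensity_histogram(quantized)))
    else:
        t = float(threshold)
    mask = quantized <= t if stain_darkens else quantized > t
    return mask, t


def coverage_stats(masks: Sequence[np.ndarray],
                   threshold_used: Optional[float] = None) -> CoverageResult:
    """Covered-area percentages of replicate masks with mean and SD.

    The SD uses the n-1 denominator and is NaN (flagged, not zero) for a
    single image.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one mask")
    pct = [100.0 * float(np.asarray(m, dtype=bool).mean()) for m in masks]
    mean = float(np.mean(pct))
    sd = float(np.std(pct, ddof=1)) if len(pct) >= 2 else float("nan")
    return CoverageResult(covered_fraction=mean, threshold_used=threshold_used,
                          n_images=len(pct), mean_pct=mean, sd_pct=sd,
                          per_image_pct=tuple(pct))


def analyze_coverage(frames: Sequence[Union[Frame, np.ndarray]],
                     threshold: Union[str, float] = "auto",
                     stain_darkens: bool = True,
                     kernel_size: int = SMOOTH_KERNEL) -> CoverageResult:
    """Full coverage pipeline over replicate micrographs."""
    masks = []
    thresholds = []
    for f in frames:
        mask, t = segment_coverage(f, threshold, stain_darkens, kernel_size)
        masks.append(mask)
        thresholds.append(t)
    t_used = float(np.mean(thresholds)) if thresholds else None
    return coverage_stats(masks, threshold_used=t_used)
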