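"""Kernel segmentation under uneven illumination.

Light across an ear is never uniform, so a single global threshold
under- or over-segments: kernels are cut out by comparing each pixel
against the mean of its local neighbourhood instead.  The neighbourhood
block size is tied to kernel geometry — the average length of the
kernels' minimum bounding rectangles, bootstrapped from a first-pass
Otsu segmentation.  The global Otsu cut is kept as the negative
control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .raster import BinaryMask, GrayImage

__all__ = [
    "KernelSizeEstimate",
    "estimate_kernel_mbr",
    "adaptive_threshold",
    "otsu_threshold",
    "round_to_odd",
]


@dataclass(frozen=True)
class KernelSizeEstimate:
    """Average kernel minimum-bounding-rectangle sides, in pixels."""

    avg_mbr_length: float
    avg_mbr_width: float
    n_components: int

    def __post_init__(self) -> None:
        if not (self.avg_mbr_length >= self.avg_mbr_width > 0):
            raise ValueError("MBR estimate requires length >= width > 0")


def round_to_odd(x: float) -> int:
    """Nearest odd integer >= 3 (window sizes must be odd)."""
    n = int(round(x))
    if n % 2 == 0:
        n += 1
    return max(n, 3)


def estimate_kernel_mbr(
    gray: GrayImage,
    fruit: BinaryMask,
    min_component_area: int = 20,
    fallback: tuple[float, float] = (11.0, 7.0),
) -> KernelSizeEstimate:
    """Bootstrap the typical kernel bounding-rectangle size from a first pass.

    Otsu-threshold the grey image inside the fruit mask, label 8-connected
    components and drop those under ``min_component_area`` pixels and the
    largest 5 % (grossly fused blobs).  Touching kernels fuse into
    components whose area is a near-integer multiple of the single-kernel
    area, so the single-kernel class is identified as the components
    whose area lies within 1.6x of the 25th-percentile area, and the
    estimate is the median of that class's bounding-box long and short
    sides (falling back to the median over all kept components when the
    class is too small).  The recognition windows must resolve the
    smallest kernel class; fused or oversized components must not
    inflate them.  With fewer than 3 usable components the configured
    ``fallback`` (length, width) is returned with a warning.
    """
    fg = fruit.as_bool

    def _fallback(reason: str) -> KernelSizeEstimate:
        warnings.warn(
            f"kernel MBR estimate fell back to defaults {fallback}: {reason}",
            stacklevel=3,
        )
        return KernelSizeEstimate(fallback[0], fallback[1], 0)

    if not fg.any():
        return _fallback("empty fruit mask")
    vals = gray.pixels[fg]
    if vals.min() == vals.max():
        return _fallback("flat grey histogram inside fruit")
    cut = threshold_otsu(np.clip(np.rint(vals), 0, 255).astype(np.uint8))
    binary = (np.rint(gray.pixels) > cut) & fg
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return _fallback("no components after thresholding")
    slices = ndimage.find_objects(labels)
    areas = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    sizes = []
    for sl, area in zip(slices, areas):
        if area < min_component_area:
            continue
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        sizes.append((max(h, w), min(h, w), area))
    if len(sizes) < 3:
        return _fallback(f"only {len(sizes)} usable components")
    sizes.sort(key=lambda t: t[2])
    n_keep = len(sizes) - max(1, int(np.ceil(0.05 * len(sizes)))) if len(sizes) > 3 else len(sizes)
    kept = sizes[:n_keep] if n_keep >= 3 else sizes
    areas = np.array([s[2] for s in kept], dtype=float)
    a_ref = float(np.quantile(areas, 0.25))
    singles = [s for s in kept if s[2] <= 1.6 * a_ref]
    if len(singles) < 3:
        singles = kept
    lengths = [s[0] for s in singles]
    widths = [s[1] for s in singles]
    return KernelSizeEstimate(
        float(np.median(lengths)), float(np.median(widths)), len(singles)
    )


def adaptive_threshold(
    gray: GrayImage, blocksize: int, fruit: BinaryMask | None = None
) -> BinaryMask:
    """Local mean threshold: foreground where a pixel strictly exceeds the
    mean of the blocksize x blocksize window centred on it.

    Windows use replicate borders and no subtractive offset; ties go to
    background (a constant region produces no foreground).  When a fruit
    mask is given the window mean is taken over fruit pixels only
    (normalised masked mean): near the silhouette an unmasked mean would
    be dragged down by the dark backdrop and spuriously mark every edge
    pixel as foreground.  Pixels outside the fruit are background.
    """
    if blocksize < 3 or blocksize % 2 == 0:
        raise ValueError("blocksize must be odd and >= 3")
    h, w = gray.pixels.shape
    if blocksize > h or blocksize > w:
        raise ValueError(f"blocksize {blocksize} exceeds image size {h}x{w}")
    px = gray.pixels
    wmask = None if fruit is None else fruit.as_bool
    if np.all(px == np.rint(px)):
        # integer-valued image: compare v * (window count) > window sum in
        # int64, so the decision is exact and a global +c offset can never
        # flip a pixel
        ones = np.ones((blocksize, blocksize), dtype=np.int64)
        vals = px.astype(np.int64)
        if wmask is None:
            win_sum = ndimage.correlate(vals, ones, mode="nearest")
            fg = vals * blocksize * blocksize > win_sum
        else:
            win_sum = ndimage.correlate(vals * wmask, ones, mode="nearest")
            win_cnt = ndimage.correlate(wmask.astype(np.int64), ones, mode="nearest")
            fg = (vals * win_cnt > win_sum) & wmask
    else:
        if wmask is None:
            local_mean = ndimage.uniform_filter(px, size=blocksize, mode="nearest")
            fg = px > local_mean
        else:
            num = ndimage.uniform_filter(px * wmask, size=blocksize, mode="nearest")
            den = ndimage.uniform_filter(
                wmask.astype(np.float64), size=blocksize, mode="nearest"
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                local_mean = np.where(den > 0, num / np.maximum(den, 1e-12), np.inf)
            fg = (px > local_mean) & wmask
    return BinaryMask.from_bool(fg)


def otsu_threshold(gray: GrayImage, fruit: BinaryMask | None = None) -> BinaryMask:
    """Global Otsu cut of the within-fruit histogram (the negative control)."""
    if fruit is None:
        fg = np.ones(gray.pixels.shape, dtype=bool)
    else:
        fg = fruit.as_bool
    vals = gray.pixels[fg]
    if vals.size == 0 or vals.min() == vals.max():
        warnings.warn(
            "single-valued histogram inside fruit; returning empty mask",
            stacklevel=2,
        )
        return BinaryMask(np.zeros(gray.pixels.shape, dtype=np.uint8))
    # integer histogram: exact maximisation over all 256 thresholds
    cut = threshold_otsu(np.clip(np.rint(vals), 0, 255).astype(np.uint8))
    return BinaryMask.from_bool((np.rint(gray.pixels) > cut) & fg)
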