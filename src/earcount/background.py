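"""Fruit/background separation.

The ear is photographed against a uniform blue (or black) backdrop.  A
joint spatial-range mean-shift filter first flattens the within-kernel
texture while keeping the fruit/background boundary sharp; the fruit is
then cut out by thresholding a single colour statistic (blue channel on
a blue backdrop, max(R, G, B) on a dark one), holes are filled and tiny
speckles removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_otsu

from .raster import BinaryMask, RgbImage, pyr_down

__all__ = [
    "MeanShiftParams",
    "BackgroundMode",
    "mean_shift_filter",
    "segment_fruit",
    "fill_holes",
    "remove_small_areas",
]


@dataclass(frozen=True)
class MeanShiftParams:
    """Joint spatial-range mean-shift window and termination settings.

    sp : spatial radius, pixels (box window of side 2*sp + 1)
    sr : colour radius, intensity units (Euclidean distance in RGB)
    max_pyramid_level : coarse-to-fine levels run before the full scale
    max_iters / convergence_eps : per-pixel termination
    """

    sp: float = 40.0
    sr: float = 60.0
    max_pyramid_level: int = 3
    max_iters: int = 5
    convergence_eps: float = 1.0

    def __post_init__(self) -> None:
        if self.sp <= 0 or self.sr <= 0:
            raise ValueError("sp and sr must be positive")
        if self.max_pyramid_level < 0:
            raise ValueError("max_pyramid_level must be >= 0")


@dataclass(frozen=True)
class BackgroundMode:
    """Which colour statistic separates fruit from backdrop.

    ``blue_background``: fruit pixels have the *lower* blue intensity.
    ``dark_background``: fruit pixels have the *higher* max(R, G, B).
    ``threshold`` fixes the cut; left None, the Otsu threshold of the
    relevant channel is used.
    """

    mode: str = "auto"
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "blue_background", "dark_background"):
            raise ValueError("mode must be auto, blue_background or dark_background")
        if self.threshold is not None and not (0 <= self.threshold <= 255):
            raise ValueError("threshold must lie in [0, 255]")


@njit(cache=True)
def _ms_pass(img, init, sp, sr, max_iters, eps):  # pragma: no cover - numba
    h, w, _ = img.shape
    out = np.empty_like(init)
    sr2 = sr * sr
    isp = int(np.ceil(sp))
    for i in range(h):
        for j in range(w):
            x = float(i)
            y = float(j)
            c0 = init[i, j, 0]
            c1 = init[i, j, 1]
            c2 = init[i, j, 2]
            # a coarse seed colour from another basin would capture the
            # wrong pixels; fall back to the pixel's own colour then
            e0 = img[i, j, 0] - c0
            e1 = img[i, j, 1] - c1
            e2 = img[i, j, 2] - c2
            if e0 * e0 + e1 * e1 + e2 * e2 > sr2:
                c0 = img[i, j, 0]
                c1 = img[i, j, 1]
                c2 = img[i, j, 2]
            for _ in range(max_iters):
                r0 = max(0, int(round(x)) - isp)
                r1 = min(h - 1, int(round(x)) + isp)
                q0 = max(0, int(round(y)) - isp)
                q1 = min(w - 1, int(round(y)) + isp)
                sx = 0.0
                sy = 0.0
                s0 = 0.0
                s1 = 0.0
                s2 = 0.0
                n = 0
                for u in range(r0, r1 + 1):
                    for v in range(q0, q1 + 1):
                        d0 = img[u, v, 0] - c0
                        d1 = img[u, v, 1] - c1
                        d2 = img[u, v, 2] - c2
                        if d0 * d0 + d1 * d1 + d2 * d2 <= sr2:
                            sx += u
                            sy += v
                            s0 += img[u, v, 0]
                            s1 += img[u, v, 1]
                            s2 += img[u, v, 2]
                            n += 1
                if n == 0:
                    break
                nx = sx / n
                ny = sy / n
                n0 = s0 / n
                n1 = s1 / n
                n2 = s2 / n
                move = abs(nx - x) + abs(ny - y)
                cmove = max(abs(n0 - c0), max(abs(n1 - c1), abs(n2 - c2)))
                x, y, c0, c1, c2 = nx, ny, n0, n1, n2
                if move + cmove < eps:
                    break
            out[i, j, 0] = c0
            out[i, j, 1] = c1
            out[i, j, 2] = c2
    return out


def _upsample_colors(colors: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour expand a colour field to a finer grid."""
    rows = np.minimum(np.arange(shape[0]) // 2, colors.shape[0] - 1)
    cols = np.minimum(np.arange(shape[1]) // 2, colors.shape[1] - 1)
    return colors[np.ix_(rows, cols)]


def mean_shift_filter(img: RgbImage, params: MeanShiftParams | None = None) -> RgbImage:
    """Replace each pixel with the colour of its mean-shift convergence point.

    Every pixel starts a mode search in the joint (row, col, R, G, B)
    space: the mean of all window pixels within spatial radius sp and
    colour radius sr is taken, the search point moves there, and the
    loop stops on convergence or after max_iters.  Run coarse-to-fine
    over ``max_pyramid_level`` pyramid layers, each finer level seeded
    with the coarser converged colours, which is what lets a modest
    max_iters reach the basin mode.
    """
    params = params or MeanShiftParams()
    full = img.pixels.astype(np.float32)
    h, w = full.shape[:2]
    # cap levels so the coarsest layer keeps a few pixels per side
    max_lvl = params.max_pyramid_level
    while max_lvl > 0 and (h >> max_lvl) < 4 or max_lvl > 0 and (w >> max_lvl) < 4:
        max_lvl -= 1
    layers = [full]
    for lvl in range(1, max_lvl + 1):
        layers.append(pyr_down(img, lvl).pixels.astype(np.float32))
    init = layers[-1].copy()
    for lvl in range(max_lvl, -1, -1):
        layer = layers[lvl]
        sp_l = max(params.sp / (2**lvl), 1.0)
        if init.shape != layer.shape:
            init = _upsample_colors(init, layer.shape[:2])
        init = _ms_pass(
            layer,
            np.ascontiguousarray(init, dtype=np.float32),
            float(sp_l),
            float(params.sr),
            int(params.max_iters),
            float(params.convergence_eps),
        )
    return RgbImage(np.clip(np.rint(init), 0, 255).astype(np.uint8))


def segment_fruit(filtered: RgbImage, bg: BackgroundMode | None = None) -> BinaryMask:
    """Threshold the mean-shift-filtered image into a fruit mask.

    On a blue backdrop the fruit has the lower blue intensity (the blue
    histogram of the filtered image is strongly bimodal); on a dark
    backdrop the fruit is simply the brighter max(R, G, B).  The cut
    defaults to the Otsu threshold of the relevant channel.
    """
    bg = bg or BackgroundMode()
    px = filtered.pixels
    mode = bg.mode
    if mode == "auto":
        # the backdrop owns the image border: blue-dominant border -> blue
        border = np.concatenate(
            [px[0], px[-1], px[:, 0], px[:, -1]], axis=0
        ).astype(np.float64)
        med = np.median(border, axis=0)
        mode = (
            "blue_background"
            if med[2] > max(med[0], med[1]) + 20
            else "dark_background"
        )
    if mode == "blue_background":
        channel = px[..., 2].astype(np.float64)
    else:
        channel = px.max(axis=-1).astype(np.float64)
    if channel.min() == channel.max():
        warnings.warn(
            "degenerate single-valued histogram; returning empty fruit mask",
            stacklevel=2,
        )
        return BinaryMask(np.zeros(channel.shape, dtype=np.uint8))
    cut = bg.threshold if bg.threshold is not None else float(threshold_otsu(channel))
    if mode == "blue_background":
        fruit = channel < cut
    else:
        fruit = channel > cut
    return BinaryMask.from_bool(fruit)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Turn background regions not connected to the border into foreground."""
    filled = ndimage.binary_fill_holes(mask.as_bool)
    return BinaryMask.from_bool(filled)


def remove_small_areas(mask: BinaryMask, min_area: int = 20) -> BinaryMask:
    """Delete 8-connected foreground components with area < min_area."""
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    kept = morphology.remove_small_objects(
        mask.as_bool, max_size=min_area - 1, connectivity=2
    )
    return BinaryMask.from_bool(kept)
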