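"""Raster types and Gaussian-pyramid compression.

High-resolution ear photographs carry far more pixels than kernel
recognition needs, so the pipeline works on a reduced Gaussian-pyramid
layer (G2 by default: 1/16 of the pixels).  Reduction convolves with a
5x5 binomial window and decimates by two per level; expansion upsamples
and convolves with the same window scaled by 4.  A Canny edge map plus
edge-pixel count serves as the diagnostic for how much kernel-boundary
information each layer retains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature
import imageio.v3 as iio

__all__ = [
    "RgbImage",
    "GrayImage",
    "BinaryMask",
    "PYRAMID_KERNEL",
    "pyramid_kernel",
    "pyr_down",
    "pyr_up",
    "compression_ratio",
    "edge_integrity",
    "psnr",
    "read_image",
    "write_image",
]


def _check_range(px: np.ndarray) -> None:
    if px.size and (px.min() < 0 or px.max() > 255):
        raise ValueError("pixel values must lie in [0, 255]")


@dataclass(frozen=True)
class RgbImage:
    """An H x W x 3 grid of 8-bit (R, G, B) intensities, (row, col) indexed."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("RgbImage requires an H x W x 3 array")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one row and column")
        _check_range(px)
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GrayImage:
    """An H x W grid of intensities in [0, 255] (float precision kept)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError("GrayImage requires an H x W array")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one row and column")
        _check_range(px)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.rint(self.pixels), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class BinaryMask:
    """An H x W grid with values in {0, 255}; foreground is 255."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("BinaryMask requires an H x W array")
        vals = np.unique(px)
        if not np.all(np.isin(vals, (0, 255))):
            raise ValueError("BinaryMask values must be 0 or 255")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @classmethod
    def from_bool(cls, fg: np.ndarray) -> "BinaryMask":
        return cls(np.where(fg, 255, 0).astype(np.uint8))

    @property
    def as_bool(self) -> np.ndarray:
        return self.pixels > 0

    @property
    def area(self) -> int:
        return int(np.count_nonzero(self.pixels))


def pyramid_kernel() -> np.ndarray:
    """The 5x5 binomial reduction window: outer([1,4,6,4,1]/16)."""
    w1 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
    return np.outer(w1, w1)


PYRAMID_KERNEL = pyramid_kernel()


def _as_planes(img):
    """Return (float planes [H, W, C], wrapper class, ndim-3 flag)."""
    if isinstance(img, RgbImage):
        return img.pixels.astype(np.float64), RgbImage, True
    if isinstance(img, GrayImage):
        return img.pixels[..., None].astype(np.float64), GrayImage, False
    raise TypeError("expected RgbImage or GrayImage")


def _wrap(planes: np.ndarray, cls, is_rgb: bool):
    planes = np.clip(planes, 0.0, 255.0)
    if is_rgb:
        return RgbImage(np.rint(planes).astype(np.uint8))
    return GrayImage(planes[..., 0])


def _reduce_once(plane: np.ndarray) -> np.ndarray:
    smoothed = ndimage.correlate(plane, PYRAMID_KERNEL, mode="nearest")
    return smoothed[::2, ::2]


def _expand_once(plane: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    # replicate-pad the source before interleaving zeros so border output
    # pixels see full kernel support (constants stay constant at the edge)
    padded = np.pad(plane, 2, mode="edge")
    up = np.zeros((2 * padded.shape[0], 2 * padded.shape[1]), dtype=np.float64)
    up[::2, ::2] = padded
    full = 4.0 * ndimage.correlate(up, PYRAMID_KERNEL, mode="constant")
    return full[4 : 4 + out_shape[0], 4 : 4 + out_shape[1]]


def pyr_down(img, levels: int):
    """Reduce ``levels`` pyramid steps; each step ceil-halves both dimensions.

    G_i(x, y) = sum_{m,n=-2..2} w(m, n) G_{i-1}(2x + m, 2y + n), with
    replicate-edge padding.  Rejects images smaller than 2**levels pixels
    in either dimension.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    planes, cls, is_rgb = _as_planes(img)
    h, w = planes.shape[:2]
    if h < 2**levels or w < 2**levels:
        raise ValueError(
            f"image of size {h}x{w} is too small for {levels} pyramid levels "
            f"(needs at least {2**levels} px per dimension)"
        )
    for _ in range(levels):
        planes = np.stack(
            [_reduce_once(planes[..., c]) for c in range(planes.shape[-1])],
            axis=-1,
        )
    return _wrap(planes, cls, is_rgb)


def pyr_up(img, levels: int, out_shape: tuple[int, int] | None = None):
    """Expand ``levels`` pyramid steps; each step doubles both dimensions.

    G_i(x, y) = 4 sum w(m, n) G_{i-1}((x+m)/2, (y+n)/2), non-integer source
    coordinates contributing zero.  ``out_shape`` pins the final (H, W) when
    round-tripping an odd-sized image.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    planes, cls, is_rgb = _as_planes(img)
    # intermediate targets: exact doubling except possibly the last step
    shapes = []
    h, w = planes.shape[:2]
    for i in range(levels):
        h, w = 2 * h, 2 * w
        shapes.append((h, w))
    if out_shape is not None:
        shapes[-1] = tuple(out_shape)
    for tgt in shapes:
        planes = np.stack(
            [_expand_once(planes[..., c], tgt) for c in range(planes.shape[-1])],
            axis=-1,
        )
    return _wrap(planes, cls, is_rgb)


def compression_ratio(original, compressed) -> float:
    """R = B'/B x 100 (%), where B counts bits: pixels x channels x 8."""

    def bits(img) -> int:
        planes, _, _ = _as_planes(img)
        return planes.shape[0] * planes.shape[1] * planes.shape[2] * 8

    b = bits(original)
    if b == 0:
        raise ValueError("original image has zero size")
    return bits(compressed) / b * 100.0


def edge_integrity(
    img: GrayImage, low: float = 80.0, high: float = 176.0
) -> tuple[BinaryMask, int]:
    """Canny edge map with hysteresis (low, high) plus its edge-pixel count.

    Used to compare how much boundary information survives at each pyramid
    layer; the default pair is low = 80 and high = 80 * 2.2.
    """
    if not (0 < low <= high <= 255):
        raise ValueError("thresholds must satisfy 0 < low <= high <= 255")
    edges = feature.canny(
        img.pixels, sigma=1.0, low_threshold=low, high_threshold=high
    )
    mask = BinaryMask.from_bool(edges)
    return mask, mask.area


def psnr(reference: GrayImage | RgbImage, test: GrayImage | RgbImage) -> float:
    """Peak signal-to-noise ratio (dB) between two same-shaped images."""
    a, _, _ = _as_planes(reference)
    b, _, _ = _as_planes(test)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(255.0**2 / mse)


def read_image(path) -> RgbImage:
    """Read a PNG/JPEG/TIFF raster as 8-bit RGB (alpha dropped, grey tiled)."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return RgbImage(arr)


def write_image(path, img) -> None:
    if isinstance(img, RgbImage):
        iio.imwrite(path, img.pixels)
    elif isinstance(img, GrayImage):
        iio.imwrite(path, img.to_uint8())
    elif isinstance(img, BinaryMask):
        iio.imwrite(path, img.pixels)
    else:
        raise TypeError("unsupported image type")
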