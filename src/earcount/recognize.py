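"""Kernel recognition by smoothed local maxima.

Touching kernels survive segmentation as fused blobs, so counting
connected components undercounts.  Instead the kernel binary image is
smoothed with a Gaussian whose window matches the average kernel width:
intensity then peaks at each kernel centre, a saddle forms across every
touching line, and one local maximum per kernel can be picked out with
a sliding block scan.  Nearby maxima from the same kernel (plateaus,
asymmetric blobs) are merged to the intensity-weighted centroid.

Two baselines used for comparison live here as well: circular Hough
detection (fails on low-roundness kernels) and iterative morphological
erosion (fails to split edge-to-edge touching pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature, transform

from .background import (
    BackgroundMode,
    MeanShiftParams,
    fill_holes,
    mean_shift_filter,
    remove_small_areas,
    segment_fruit,
)
from .config import PipelineConfig
from .enhance import (
    build_od_matrix,
    color_deconvolve,
    extract_gray,
    rgb_to_lab,
    select_stain_combination,
)
from .raster import BinaryMask, GrayImage, RgbImage, pyr_down
from .segment import adaptive_threshold, estimate_kernel_mbr, round_to_odd

__all__ = [
    "RecognitionPoint",
    "DetectionResult",
    "gaussian_smooth",
    "find_local_maxima",
    "eliminate_spurious",
    "count_kernels",
    "hough_baseline",
    "erosion_separation_count",
    "PipelineError",
]


class PipelineError(RuntimeError):
    """A stage of count_kernels failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RecognitionPoint:
    """A recognised kernel centre, (row, col) 0-based pixel coordinates."""

    row: float
    col: float
    peak_value: float

    def __post_init__(self) -> None:
        if self.peak_value <= 0:
            raise ValueError("peak_value must be positive")


@dataclass
class DetectionResult:
    """Recognised points and count, plus optional per-stage intermediates."""

    points: list[RecognitionPoint]
    count: int
    stage_images: dict = field(default_factory=dict)
    config_used: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "count": self.count,
            "points": [
                {"row": p.row, "col": p.col, "peak_value": p.peak_value}
                for p in self.points
            ],
            "config": self.config_used,
        }


def gaussian_smooth(mask: BinaryMask, window: int) -> GrayImage:
    """Smooth the kernel binary image with an N x N Gaussian (sigma = N/6).

    The window is rounded up to odd, the kernel truncated at the window
    edge and borders replicated.  Within an isolated convex blob the
    result is maximal at an interior point, which is what makes the
    centre of each kernel detectable.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    if window % 2 == 0:
        window += 1
    sigma = window / 6.0
    radius = window // 2
    smoothed = ndimage.gaussian_filter(
        mask.pixels.astype(np.float64),
        sigma=sigma,
        mode="nearest",
        truncate=radius / sigma,
    )
    return GrayImage(np.clip(smoothed, 0.0, 255.0))


def find_local_maxima(smoothed: GrayImage, block: int) -> list[RecognitionPoint]:
    """Initial recognition points: maxima of an L x L sliding block scan.

    A pixel qualifies when its value is >= every value in the block
    centred on it, strictly greater than at least one of them, and
    positive.  A plateau of equal-valued qualifying pixels contributes
    only its member closest to the plateau centroid; the merge step
    afterwards makes the final result independent of that choice.
    """
    if block < 3:
        raise ValueError("block must be >= 3")
    if block % 2 == 0:
        block += 1
    v = smoothed.pixels
    mx = ndimage.maximum_filter(v, size=block, mode="nearest")
    mn = ndimage.minimum_filter(v, size=block, mode="nearest")
    cand = (v >= mx) & (mn < v) & (v > 0)
    if not cand.any():
        return []
    # adjacent qualifying pixels necessarily share a value (each lies in
    # the other's block), so connected candidate regions are plateaus
    labels, n = ndimage.label(cand, structure=np.ones((3, 3), dtype=int))
    points: list[RecognitionPoint] = []
    for idx in range(1, n + 1):
        rows, cols = np.nonzero(labels == idx)
        cr, cc = rows.mean(), cols.mean()
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        k = int(np.argmin(d2))  # ties: first in scan order
        points.append(
            RecognitionPoint(float(rows[k]), float(cols[k]), float(v[rows[k], cols[k]]))
        )
    points.sort(key=lambda p: (p.row, p.col))
    return points


def eliminate_spurious(
    points: list[RecognitionPoint],
    smoothed: GrayImage,
    block: int,
    merge_radius_factor: float = 0.5,
    block_rows: int | None = None,
) -> list[RecognitionPoint]:
    """Merge recognition points inside one kernel's footprint and
    reposition each survivor at the centroid of its local block.

    Points are single-linkage clustered when they fall inside the same
    merge ellipse — semi-axes factor * block_rows along rows and
    factor * block along columns, matching the kernel bounding
    rectangle (``block_rows`` defaults to ``block``, the isotropic
    radius factor * L).  Each cluster collapses to its
    intensity-weighted centroid, repeating until no pair is closer than
    the merge region, so several maxima on one elongated kernel end as
    a single recognition point while points on neighbouring kernels
    stay distinct.  Each final point is then moved to the
    intensity-weighted centroid of the L x L block around it, which
    centres it on the kernel at sub-pixel precision.
    """
    rad_c = merge_radius_factor * block
    rad_r = merge_radius_factor * (block_rows if block_rows is not None else block)
    pts = [(p.row, p.col, p.peak_value) for p in points]
    while True:
        n = len(pts)
        if n <= 1:
            break
        parent = list(range(n))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        merged_any = False
        for i in range(n):
            for j in range(i + 1, n):
                dr = (pts[i][0] - pts[j][0]) / rad_r
                dc = (pts[i][1] - pts[j][1]) / rad_c
                if dr * dr + dc * dc < 1.0:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
                        merged_any = True
        if not merged_any:
            break
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        new_pts = []
        for members in groups.values():
            wsum = sum(pts[i][2] for i in members)
            r = sum(pts[i][0] * pts[i][2] for i in members) / wsum
            c = sum(pts[i][1] * pts[i][2] for i in members) / wsum
            new_pts.append((r, c, max(pts[i][2] for i in members)))
        pts = new_pts
    # local-block centroid refinement
    v = smoothed.pixels
    h, w = v.shape
    half = block // 2
    refined = []
    for r, c, pv in pts:
        ri, ci = int(round(r)), int(round(c))
        r0, r1 = max(0, ri - half), min(h, ri + half + 1)
        c0, c1 = max(0, ci - half), min(w, ci + half + 1)
        patch = v[r0:r1, c0:c1]
        total = patch.sum()
        if total > 0:
            rows = np.arange(r0, r1, dtype=float)
            cols = np.arange(c0, c1, dtype=float)
            r = float(rows @ patch.sum(axis=1) / total)
            c = float(patch.sum(axis=0) @ cols / total)
        refined.append((r, c, pv))
    out = [RecognitionPoint(r, c, pv) for r, c, pv in refined]
    out.sort(key=lambda p: (p.row, p.col))
    return out


def _run_stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:  # attach the stage name for diagnosis
        raise PipelineError(name, exc) from exc


def count_kernels(
    img: RgbImage,
    config: PipelineConfig | None = None,
    keep_stages: bool = False,
) -> DetectionResult:
    """Run the full five-step pipeline and return the kernel count.

    pyramid compression -> mean-shift filtering + fruit segmentation ->
    colour-deconvolution enhancement -> adaptive-threshold segmentation
    -> smoothed local-maxima recognition.  Points are reported in
    original-image coordinates.
    """
    config = config or PipelineConfig()
    stages: dict = {}
    level = config.pyramid_level
    work = _run_stage("pyr_down", pyr_down, img, level) if level >= 1 else img
    if keep_stages:
        stages["compressed"] = work

    ms = MeanShiftParams(
        sp=max(config.mean_shift_sp / (2**level), 1.0),
        sr=config.mean_shift_sr,
        # the filter's internal pyramid levels are defined from the original
        # scale; working on an already-compressed layer uses what remains
        max_pyramid_level=max(0, config.mean_shift_max_pyramid_level - level),
        max_iters=config.mean_shift_max_iters,
        convergence_eps=config.mean_shift_eps,
    )
    filtered = _run_stage("mean_shift_filter", mean_shift_filter, work, ms)
    if keep_stages:
        stages["filtered"] = filtered

    bg = BackgroundMode(mode=config.background_mode, threshold=config.background_threshold)
    fruit = _run_stage("segment_fruit", segment_fruit, filtered, bg)
    fruit = _run_stage("fill_holes", fill_holes, fruit)
    fruit = _run_stage("remove_small_areas", remove_small_areas, fruit, config.min_area)
    if keep_stages:
        stages["fruit_mask"] = fruit

    empty = DetectionResult(points=[], count=0, stage_images=stages, config_used=config.snapshot())
    if not fruit.as_bool.any():
        return empty

    lab = _run_stage("rgb_to_lab", rgb_to_lab, filtered)
    combo = _run_stage(
        "select_stain_combination",
        select_stain_combination,
        lab,
        fruit,
        config.stain_library(),
    )
    od = _run_stage("build_od_matrix", build_od_matrix, combo)
    maps = _run_stage("color_deconvolve", color_deconvolve, lab, od)
    gray = _run_stage("extract_gray", extract_gray, maps, combo)
    if keep_stages:
        stages["stain"] = combo.name
        stages["enhanced"] = gray

    est = _run_stage(
        "estimate_kernel_mbr",
        estimate_kernel_mbr,
        gray,
        fruit,
        config.min_area,
        config.fallback_mbr,
    )
    blocksize = config.blocksize or round_to_odd(est.avg_mbr_length)
    binary = _run_stage("adaptive_threshold", adaptive_threshold, gray, blocksize, fruit)
    binary = _run_stage("remove_small_areas", remove_small_areas, binary, config.min_area)
    if keep_stages:
        stages["kernel_binary"] = binary

    if not binary.as_bool.any():
        empty.stage_images = stages
        return empty

    window = config.gaussian_window or round_to_odd(est.avg_mbr_width)
    smoothed = _run_stage("gaussian_smooth", gaussian_smooth, binary, window)
    local_block = config.local_block or round_to_odd(est.avg_mbr_width)
    pts = _run_stage("find_local_maxima", find_local_maxima, smoothed, local_block)
    pts = _run_stage(
        "eliminate_spurious",
        eliminate_spurious,
        pts,
        smoothed,
        local_block,
        config.merge_radius_factor,
        round_to_odd(est.avg_mbr_length),
    )
    if keep_stages:
        stages["smoothed"] = smoothed

    scale = 2**level
    offset = (scale - 1) / 2.0
    mapped = [
        RecognitionPoint(p.row * scale + offset, p.col * scale + offset, p.peak_value)
        for p in pts
    ]
    return DetectionResult(
        points=mapped,
        count=len(mapped),
        stage_images=stages,
        config_used=config.snapshot(),
    )


def hough_baseline(
    gray: GrayImage,
    fruit: BinaryMask | None,
    r_min: float,
    r_max: float,
    accumulator_threshold: float = 0.45,
    canny_low: float = 80.0,
    canny_high: float = 176.0,
) -> list[RecognitionPoint]:
    """Circular-Hough comparison baseline.

    Runs a gradient Canny edge map through the circular Hough transform
    over integer radii in [r_min, r_max] and keeps accumulator peaks
    above ``accumulator_threshold`` (normalised).  Low-roundness kernels
    are expected to be missed or split — that failure mode is the reason
    the local-maxima recogniser exists.
    """
    if not (0 < r_min < r_max):
        raise ValueError("need 0 < r_min < r_max")
    edges = feature.canny(
        gray.pixels, sigma=1.0, low_threshold=canny_low, high_threshold=canny_high
    )
    if fruit is not None:
        edges &= fruit.as_bool
    if not edges.any():
        return []
    radii = np.arange(max(1, int(np.floor(r_min))), int(np.ceil(r_max)) + 1)
    acc = transform.hough_circle(edges, radii)
    accums, cols, rows, _ = transform.hough_circle_peaks(
        acc,
        radii,
        min_xdistance=int(round(r_min)),
        min_ydistance=int(round(r_min)),
        threshold=accumulator_threshold * acc.max(),
    )
    points = []
    h, w = gray.pixels.shape
    for a, c, r in zip(accums, cols, rows):
        if 0 <= r < h and 0 <= c < w and a > 0:
            if fruit is None or fruit.as_bool[int(r), int(c)]:
                points.append(RecognitionPoint(float(r), float(c), float(a)))
    return points


def erosion_separation_count(
    mask: BinaryMask, max_iters: int = 50, min_fragment: int = 4
) -> int:
    """Morphological-corrosion baseline: erode 3x3 until the blob splits.

    Returns the number of fragments (each >= min_fragment pixels) the
    first time more than one appears; returns 1 if the blob erodes away
    without ever splitting — the documented failure on edge-to-edge
    touching pairs.
    """
    current = mask.as_bool
    structure = np.ones((3, 3), dtype=bool)
    for _ in range(max_iters):
        labels, n = ndimage.label(current, structure=structure)
        if n >= 2:
            areas = ndimage.sum_labels(current, labels, index=np.arange(1, n + 1))
            big = int(np.sum(areas >= min_fragment))
            if big >= 2:
                return big
        if not current.any():
            return 1
        current = ndimage.binary_erosion(current, structure=structure)
    return 1
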