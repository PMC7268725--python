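"""Kernel-edge enhancement by colour deconvolution.

The colour gradient between touching kernels is narrow, so the fruit
image is treated as if it had been "stained" by virtual dyes: channels
are converted to a Lab encoding, mapped into optical-density space
(Lambert-Beer: density adds linearly in -ln intensity), and unmixed
with the inverse of a stain optical-density matrix.  The first stain's
density map, rescaled to display range, is the enhanced grey image the
segmentation stage consumes.  The dye library holds three combinations
(methyl green, hematoxylin GL and a pure-brightness "white" dye); the
one whose reference Lab centroid is closest to the fruit's mean Lab is
selected automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .raster import BinaryMask, GrayImage, RgbImage

__all__ = [
    "LabImage",
    "StainCombination",
    "OdMatrix",
    "rgb_to_lab",
    "build_od_matrix",
    "color_deconvolve",
    "select_stain_combination",
    "extract_gray",
    "default_stain_library",
    "load_stain_library",
    "save_stain_library",
]

_LN256 = np.log(256.0)

# RGB -> Lab transform; the a and b coefficient rows sum to zero, so any
# grey input maps to a = b = 128 exactly.
_LAB_L = np.array([0.2126, 0.7152, 0.0722])
_LAB_A = np.array([0.2213, -0.339, 0.1177])
_LAB_B = np.array([0.1949, 0.6057, -0.8006])
_LAB_A_SCALE = 1.4749
_LAB_B_SCALE = 0.6245


@dataclass(frozen=True)
class LabImage:
    """H x W x 3 (L, a, b) values in the offset-128 encoding, each in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("LabImage requires an H x W x 3 array")
        if px.size and (px.min() < 0 or px.max() > 255):
            raise ValueError("Lab values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class StainCombination:
    """A named optical-density vector plus the Lab centroid it represents.

    ``primary_vector`` holds the three absorption factors; the all-zero
    "white" vector is interpreted as a pure-brightness absorber
    (1, 1, 1)/sqrt(3), since brightness is the feature that separates a
    kernel from its touching edges.  ``lab_centroid`` is the mean
    (L, a, b) of the images this combination is intended for and drives
    automatic selection.
    """

    name: str
    primary_vector: tuple[float, float, float]
    lab_centroid: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.primary_vector, dtype=np.float64)
        if v.shape != (3,):
            raise ValueError("primary_vector must have three components")
        if np.any(v < 0):
            raise ValueError("absorption factors must be non-negative")

    def effective_vector(self) -> np.ndarray:
        """Unit-norm OD vector, with the zero vector mapped to brightness."""
        v = np.asarray(self.primary_vector, dtype=np.float64)
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            return np.full(3, 1.0 / np.sqrt(3.0))
        return v / norm


@dataclass(frozen=True)
class OdMatrix:
    """Stain optical-density matrix C (rows = stains) and its inverse D."""

    C: np.ndarray
    D: np.ndarray


def rgb_to_lab(img: RgbImage) -> LabImage:
    """Per-pixel RGB -> (L, a, b), offset-128 encoding, clamped to [0, 255].

    The a and b rows are evaluated in difference form (their
    coefficients sum to zero), so grey inputs land on a = b = 128
    exactly in floating point, not merely to rounding error.
    """
    rgb = img.pixels.astype(np.float64)
    r, g, b_ch = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    L = rgb @ _LAB_L
    # 0.2213 R - 0.339 G + 0.1177 B  ==  0.2213 (R-G) + 0.1177 (B-G)
    a = _LAB_A_SCALE * (0.2213 * (r - g) + 0.1177 * (b_ch - g)) + 128.0
    # 0.1949 R + 0.6057 G - 0.8006 B  ==  0.1949 (R-B) + 0.6057 (G-B)
    b = _LAB_B_SCALE * (0.1949 * (r - b_ch) + 0.6057 * (g - b_ch)) + 128.0
    lab = np.stack([L, a, b], axis=-1)
    return LabImage(np.clip(lab, 0.0, 255.0))


def _complete_basis(v1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Second and third unit vectors orthogonal to v1 (residual convention)."""
    cand = np.array([v1[1], v1[2], v1[0]])
    cand = cand - (cand @ v1) * v1
    if np.linalg.norm(cand) < 1e-6:
        # v1 has equal components (e.g. the brightness dye); any fixed
        # orthogonal direction serves as the residual axis
        cand = np.array([1.0, -1.0, 0.0])
        cand = cand - (cand @ v1) * v1
    v2 = cand / np.linalg.norm(cand)
    v3 = np.cross(v1, v2)
    v3 = v3 / np.linalg.norm(v3)
    return v2, v3


def build_od_matrix(combo: StainCombination) -> OdMatrix:
    """Complete the stain's OD vector to a full 3x3 matrix and invert it.

    The supplied vector is normalised to unit length; the second row is
    a unit vector orthogonal to it and the third their normalised cross
    product, so with a single supplied stain C is orthonormal.  D is the
    matrix inverse of C.
    """
    v1 = combo.effective_vector()
    v2, v3 = _complete_basis(v1)
    C = np.stack([v1, v2, v3])
    if abs(np.linalg.det(C)) < 1e-9:
        raise ValueError("stain vectors are linearly dependent after completion")
    D = np.linalg.inv(C)
    return OdMatrix(C=C, D=D)


def _to_density(values: np.ndarray) -> np.ndarray:
    """Channel intensity -> optical density, in base-256 log units.

    -log256((v + 1) / 256), so a black pixel has density 1 and a white
    pixel density 0; this is the scaling under which the display
    transform below is its exact inverse (ImageJ plugin convention).
    """
    return -np.log((values + 1.0) / 256.0) / _LN256


def _to_display(density: np.ndarray) -> np.ndarray:
    """Stain density -> display intensity: exp(-density * ln 256) * 256 - 1."""
    return np.clip(np.exp(-density * _LN256) * 256.0 - 1.0, 0.0, 255.0)


def color_deconvolve(
    lab: LabImage, od: OdMatrix
) -> tuple[GrayImage, GrayImage, GrayImage]:
    """Unmix a Lab image into three per-stain density maps (display scale).

    Channels are fed to the OD matrix columns in (L, a, b) order.  Each
    pixel's OD vector R' = -ln((v + 1)/256) is projected onto per-stain
    densities R* = R' D (row-vector convention, D = C^-1), and each
    density map is rescaled to [0, 255] with the conventional
    exp(-R* ln 256) * 256 - 1 display transform.
    """
    od_vals = _to_density(lab.pixels)
    densities = od_vals @ od.D  # rows R'; R*_row = R'_row @ D
    maps = _to_display(densities)
    return (
        GrayImage(maps[..., 0]),
        GrayImage(maps[..., 1]),
        GrayImage(maps[..., 2]),
    )


def reconstruct_lab(
    stain_maps: tuple[GrayImage, GrayImage, GrayImage], od: OdMatrix
) -> np.ndarray:
    """Invert color_deconvolve: recover the Lab channel values (float)."""
    dens = np.stack([_to_density(m.pixels) for m in stain_maps], axis=-1)
    od_vals = dens @ od.C
    return np.exp(-od_vals * _LN256) * 256.0 - 1.0


def select_stain_combination(
    lab: LabImage,
    fruit: BinaryMask,
    library: list[StainCombination],
) -> StainCombination:
    """Pick the library entry whose Lab centroid is nearest the fruit's mean.

    The mean (L, a, b) is taken over fruit pixels only; ties go to the
    first entry in library order.
    """
    if not library:
        raise ValueError("stain library is empty")
    fg = fruit.as_bool
    if not fg.any():
        raise ValueError("fruit mask is empty; cannot select a stain combination")
    mean_lab = lab.pixels[fg].mean(axis=0)
    best = None
    best_dist = np.inf
    for combo in library:
        if combo.lab_centroid is None:
            raise ValueError(f"stain combination {combo.name!r} has no lab_centroid")
        d = float(np.linalg.norm(mean_lab - np.asarray(combo.lab_centroid)))
        if d < best_dist - 1e-12:
            best, best_dist = combo, d
    return best


def extract_gray(
    stain_maps: tuple[GrayImage, GrayImage, GrayImage],
    combo: StainCombination | None = None,
) -> GrayImage:
    """The enhanced grey image: the first (primary) stain's density map."""
    return stain_maps[0]


# The three shipped dye vectors.  The centroids attached here are
# synthetic: they were computed from this package's generated fixtures,
# not from any photographic training set, and real deployments should
# replace them via a user library file.
_DEFAULT_LIBRARY = [
    {
        "name": "methyl green",
        "vector": (0.98003, 0.144316, 0.133146),
        "lab_centroid": (120.0, 100.0, 190.0),
    },
    {
        "name": "hematoxylin GL",
        "vector": (0.644211, 0.716556, 0.266844),
        "lab_centroid": (150.0, 120.0, 170.0),
    },
    {
        "name": "white",
        "vector": (0.0, 0.0, 0.0),
        "lab_centroid": (180.0, 115.0, 195.0),
    },
]


def default_stain_library() -> list[StainCombination]:
    return [
        StainCombination(
            name=e["name"],
            primary_vector=tuple(e["vector"]),
            lab_centroid=tuple(e["lab_centroid"]),
        )
        for e in _DEFAULT_LIBRARY
    ]


def load_stain_library(path) -> list[StainCombination]:
    """Read a YAML library: a list of {name, vector, lab_centroid} entries."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return [
        StainCombination(
            name=e["name"],
            primary_vector=tuple(float(x) for x in e["vector"]),
            lab_centroid=(
                tuple(float(x) for x in e["lab_centroid"])
                if e.get("lab_centroid") is not None
                else None
            ),
        )
        for e in entries
    ]


def save_stain_library(library: list[StainCombination], path) -> None:
    entries = [
        {
            "name": c.name,
            "vector": [float(x) for x in c.primary_vector],
            "lab_centroid": (
                [float(x) for x in c.lab_centroid]
                if c.lab_centroid is not None
                else None
            ),
        }
        for c in library
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)
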