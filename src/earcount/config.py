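"""Pipeline configuration.

Every tunable of the counting pipeline lives here with its default:
the working pyramid layer (G2), the mean-shift radii (sp = 40 px at
original scale, sr = 60 intensity units), the small-area cut (20 px),
the Canny hysteresis pair (80, 176) and the recognition-window
overrides.  Window sizes left at None are derived per image from the
bootstrapped kernel MBR estimate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from . import enhance

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # compression
    pyramid_level: int = 2
    # mean-shift filtering (sp is given at original scale and is divided
    # by the compression factor when the pipeline works on a reduced layer)
    mean_shift_sp: float = 40.0
    mean_shift_sr: float = 60.0
    mean_shift_max_pyramid_level: int = 3
    mean_shift_max_iters: int = 5
    mean_shift_eps: float = 1.0
    # background separation
    background_mode: str = "auto"
    background_threshold: float | None = None
    min_area: int = 20
    # edge diagnostic
    canny_low: float = 80.0
    canny_high: float = 176.0
    # enhancement
    stain_library_path: str | None = None
    # segmentation / recognition windows (None = derive from MBR estimate)
    blocksize: int | None = None
    gaussian_window: int | None = None
    local_block: int | None = None
    merge_radius_factor: float = 0.5
    # fallback kernel MBR (length, width) at the working resolution, used
    # when too few components survive the bootstrap estimate; matches a
    # typical 44 x 28 px kernel seen at the G2 layer
    fallback_mbr: tuple[float, float] = (11.0, 7.0)
    # Hough baseline: radii bounds as fractions of avg MBR width, and the
    # normalised accumulator threshold (fixed on the fixture suite)
    hough_radius_fractions: tuple[float, float] = (0.3, 0.7)
    hough_accumulator_threshold: float = 0.45
    debug_dir: str | None = None

    def stain_library(self):
        if self.stain_library_path is not None:
            return enhance.load_stain_library(self.stain_library_path)
        return enhance.default_stain_library()

    def snapshot(self) -> dict:
        d = asdict(self)
        d["fallback_mbr"] = list(self.fallback_mbr)
        d["hough_radius_fractions"] = list(self.hough_radius_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "fallback_mbr" in d and d["fallback_mbr"] is not None:
            d["fallback_mbr"] = tuple(d["fallback_mbr"])
        if "hough_radius_fractions" in d and d["hough_radius_fractions"] is not None:
            d["hough_radius_fractions"] = tuple(d["hough_radius_fractions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.snapshot(), fh, sort_keys=False)
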