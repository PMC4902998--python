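"""Raster and result I/O plus pipeline configuration.

Micrographs are bright-field, 8-bit monochrome frames (nominally 1392 x 1040
px, pixel pitch 6.45 um, x40 magnification).  Intensities are normalised to
[0, 1] at load time; every threshold in :class:`PipelineConfig` is expressed
on that unit scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GrayImage",
    "PipelineConfig",
    "load_gray_image",
    "save_gray_image",
    "load_mask",
    "save_mask",
    "write_filament_csv",
    "read_filament_csv",
]


@dataclass
class GrayImage:
    """A 2-D intensity field in [0, 1] with imaging metadata.

    ``downsample_factor`` records how far the pixel grid is from the native
    sensor resolution: 1 for a raw frame, 2 after the pipeline's bicubic
    resize.  Physical length conversions use it together with the pixel
    pitch and magnification.
    """

    pixels: np.ndarray
    pixel_pitch_um: float = 6.45
    magnification: float = 40.0
    downsample_factor: int = 1
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("GrayImage requires a 2-D pixel field")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities must lie in [0, 1], got [{lo}, {hi}]")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray, **changes) -> "GrayImage":
        return replace(self, pixels=pixels, **changes)


@dataclass
class PipelineConfig:
    """Thresholds and structural parameters of the detection pipeline.

    Defaults reproduce the ROC-optimal operating point (variance 10.5e-4,
    distance 6.4 px, RRG 3.2) together with the size rules derived from the
    smallest expected filament (0.8 um diameter, 10 um length).
    """

    gamma: float = 0.6
    boost: float = 1.0
    se_radius: int = 3
    variance_window: int = 3
    variance_threshold: float = 10.5e-4
    distance_threshold: float = 6.4
    floc_dilation_radius: float | None = None  # None -> distance_threshold
    rrg_threshold: float = 3.2
    min_area_px: int = 77
    min_filament_len_px: int = 31
    max_hole_diameter_px: float = 2.5
    eval_dilation_radius_px: int = 3
    downsample_factor: int = 2
    sample_variance: bool = False  # population (n) normalisation by default

    def __post_init__(self) -> None:
        for name in ("gamma", "variance_threshold", "distance_threshold", "rrg_threshold",
                     "max_hole_diameter_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_area_px < 1 or self.se_radius < 1 or self.downsample_factor < 1:
            raise ValueError("min_area_px, se_radius and downsample_factor must be >= 1")
        if self.variance_window % 2 == 0 or self.variance_window < 3:
            raise ValueError("variance_window must be odd and >= 3")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def load_gray_image(path: str | Path, *, pixel_pitch_um: float = 6.45,
                    magnification: float = 40.0,
                    downsample_factor: int = 1) -> GrayImage:
    """Read a TIFF/PNG/BMP micrograph and normalise it to [0, 1].

    Multi-channel rasters are converted by the luminance average with a
    warning.  Integer formats are divided by their type maximum so that an
    8-bit value of 255 maps to intensity 1.0.
    """
    arr = iio.imread(path)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    if arr.ndim == 3:
        warnings.warn(f"{path}: multi-channel input converted by luminance average",
                      stacklevel=2)
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise IOError(f"{path}: expected a 2-D raster, got shape {arr.shape}")
    return GrayImage(arr, pixel_pitch_um=pixel_pitch_um, magnification=magnification,
                     downsample_factor=downsample_factor, image_id=Path(path).stem)


def save_gray_image(image: GrayImage, path: str | Path) -> None:
    """Write an image as 8-bit grayscale (format chosen by extension)."""
    arr = np.clip(np.round(image.pixels * 255), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask (any nonzero pixel is object)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return arr > 0


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


_FILAMENT_COLUMNS = ["image_id", "filament_index", "length_um", "rrg", "spine_px"]
_SUMMARY_COLUMNS = ["image_id", "n_filaments", "tefl_um"]


def write_filament_csv(records, path: str | Path) -> None:
    """Write one row per filament plus a per-image summary table.

    The summary (filament count and TEFL, the per-image total extended
    filament length in um) goes to ``<stem>_summary.csv`` next to the main
    file.  UTF-8, header row, '.' decimal separator.
    """
    path = Path(path)
    rows = []
    for i, rec in enumerate(records):
        rows.append({"image_id": rec.image_id, "filament_index": i,
                     "length_um": rec.length_um, "rrg": rec.rrg,
                     "spine_px": len(rec.spine.path)})
    df = pd.DataFrame(rows, columns=_FILAMENT_COLUMNS)
    df.to_csv(path, index=False)
    if len(df):
        summary = (df.groupby("image_id", sort=False)
                     .agg(n_filaments=("filament_index", "size"),
                          tefl_um=("length_um", "sum"))
                     .reset_index())
    else:
        summary = pd.DataFrame(columns=_SUMMARY_COLUMNS)
    summary.to_csv(path.with_name(path.stem + "_summary.csv"), index=False)


def read_filament_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
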