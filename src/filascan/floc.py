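"""Thickness-based separation of flocs from filaments.

Without staining or phase contrast the only reliable cue distinguishing a
compact microbial aggregate (floc) from a filament is thickness.  The
Euclidean distance transform assigns every object pixel its distance to
the nearest background pixel; thresholding it keeps only the eroded cores
of thick objects, and a dilation of equal radius approximately restores
their original extent.  A binary AND with the complement then strips the
flocs from the mask, leaving thin components only.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["euclidean_distance_map", "extract_floc_mask", "remove_flocs",
           "dilate_by_radius"]


def _as_bool(mask) -> np.ndarray:
    for attr in ("values", "pixels"):
        if hasattr(mask, attr):
            mask = getattr(mask, attr)
    return np.asarray(mask, bool)


def euclidean_distance_map(mask) -> np.ndarray:
    """Exact Euclidean distance from each object pixel to the background."""
    return ndimage.distance_transform_edt(_as_bool(mask))


def dilate_by_radius(mask, radius: float) -> np.ndarray:
    """Binary dilation with an exact Euclidean disc of real-valued radius."""
    mask = _as_bool(mask)
    if radius <= 0 or not mask.any():
        return mask.copy()
    return ndimage.distance_transform_edt(~mask) <= radius


def extract_floc_mask(distmap, distance_threshold: float,
                      dilation_radius: float | None = None) -> np.ndarray:
    """Identify flocs as thick cores grown back to their original extent.

    Pixels at distance >= ``distance_threshold`` from the background form
    the eroded floc cores; dilating them by ``dilation_radius`` (default:
    the threshold itself, matching the erosion depth) reconstructs the
    approximate floc footprint.
    """
    if distance_threshold <= 0:
        raise ValueError("distance_threshold must be > 0")
    if dilation_radius is None:
        dilation_radius = distance_threshold
    distmap = distmap.values if hasattr(distmap, "values") else np.asarray(distmap, float)
    return dilate_by_radius(distmap >= distance_threshold, dilation_radius)


def remove_flocs(mask, floc_mask) -> np.ndarray:
    """mask AND NOT floc_mask — strip floc regions from the binary image."""
    mask, floc_mask = _as_bool(mask), _as_bool(floc_mask)
    if mask.shape != floc_mask.shape:
        raise ValueError("mask and floc_mask shapes differ")
    return mask & ~floc_mask
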