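"""Variance-transform binarization and mask clean-up.

The in-focus slab of the suspension (the "virtual sample volume") is
defined purely optically: sharp objects produce strong local intensity
transitions, blurred out-of-focus objects do not.  Thresholding the local
variance in a small window with one fixed value therefore selects the same
sample volume in every frame, which is what makes per-image filament
totals comparable across a measurement campaign.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import morphology

__all__ = [
    "variance_transform",
    "binarize",
    "remove_small_objects",
    "fill_small_holes",
]


def _as_array(image) -> np.ndarray:
    for attr in ("pixels", "values"):
        if hasattr(image, attr):
            return getattr(image, attr)
    return np.asarray(image, float)


def variance_transform(image, window: int = 3, *, sample: bool = False) -> np.ndarray:
    """Per-pixel variance of the ``window`` x ``window`` neighbourhood.

    Population (n) normalisation by default; ``sample=True`` switches to
    the n-1 estimator.  Reflect padding at the borders.  The map is zero
    wherever the neighbourhood is constant and large across sharp edges,
    which is what makes it a focus detector.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    g = _as_array(image)
    mean = ndimage.uniform_filter(g, size=window, mode="reflect")
    mean_sq = ndimage.uniform_filter(g * g, size=window, mode="reflect")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    if sample:
        n = window * window
        var = var * (n / (n - 1))
    return var


def binarize(varmap, variance_threshold: float) -> np.ndarray:
    """Threshold the variance map: object iff variance >= threshold.

    Strongly blurred structures never reach the threshold and are thereby
    excluded from the virtual sample volume.
    """
    if variance_threshold <= 0:
        raise ValueError("variance_threshold must be > 0")
    return _as_array(varmap) >= variance_threshold


def remove_small_objects(mask, min_area_px: int = 77) -> np.ndarray:
    """Delete 8-connected components with fewer than ``min_area_px`` pixels.

    The default 77 comes from the smallest plausible filament footprint
    (~2.5 px width x 31 px length).
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    mask = np.asarray(_as_array(mask), bool)
    # skimage's max_size semantics remove components <= the value
    return morphology.remove_small_objects(mask, max_size=min_area_px - 1,
                                           connectivity=2)


def fill_small_holes(mask, max_hole_diameter_px: float = 2.5) -> np.ndarray:
    """Restricted hole filling.

    Only interior background components (4-connected, not touching the
    image border) whose equivalent-area diameter ``2*sqrt(area/pi)`` is
    below the cut-off are converted to object.  Larger enclosed regions —
    typically loops formed by curved filaments — are left open on purpose.
    """
    if max_hole_diameter_px <= 0:
        raise ValueError("max_hole_diameter_px must be > 0")
    mask = np.asarray(_as_array(mask), bool)
    holes, n = ndimage.label(~mask, structure=np.array([[0, 1, 0],
                                                        [1, 1, 1],
                                                        [0, 1, 0]]))
    if n == 0:
        return mask.copy()
    border_labels = np.unique(np.concatenate([
        holes[0, :], holes[-1, :], holes[:, 0], holes[:, -1]]))
    areas = np.bincount(holes.ravel(), minlength=n + 1)
    fill = (areas > 0) & (2.0 * np.sqrt(areas / np.pi) < max_hole_diameter_px)
    fill[0] = False
    fill[border_labels] = False
    return mask | fill[holes]
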