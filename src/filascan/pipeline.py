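"""The full detection pipeline and batch driver.

Stage order is fixed: bicubic resize -> gamma correction -> high-boost +
top/bottom-hat enhancement -> variance-transform binarization -> size
filter -> restricted hole filling -> distance-map floc removal ->
skeletonization -> geodesic spine extraction with branch reprocessing ->
RRG filter -> physical length conversion.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classify, floc, preprocess, segmentation, spine as spine_mod
from .classify import FilamentRecord, ScaleParams, tefl
from .io import GrayImage, PipelineConfig, load_gray_image

__all__ = ["StageTrace", "BatchSummary", "process_image", "process_batch",
           "detection_mask"]

logger = logging.getLogger("filascan")


@dataclass
class StageTrace:
    """Intermediate results and per-stage wall time, in stage order."""

    enhanced: np.ndarray | None = None
    variance_map: np.ndarray | None = None
    binary_mask: np.ndarray | None = None
    cleaned_mask: np.ndarray | None = None
    floc_mask: np.ndarray | None = None
    thin_mask: np.ndarray | None = None
    skeletons: list = field(default_factory=list)
    spines: list = field(default_factory=list)
    records: list = field(default_factory=list)
    timings_s: dict[str, float] = field(default_factory=dict)


@dataclass
class BatchSummary:
    """Per-image filament records and totals plus the batch mean TEFL."""

    image_ids: list[str]
    records: list[FilamentRecord]
    per_image_tefl_um: dict[str, float]
    otefl_um: float
    skipped: list[str] = field(default_factory=list)


def process_image(image: GrayImage, config: PipelineConfig | None = None
                  ) -> tuple[list[FilamentRecord], StageTrace]:
    """Run every stage on one image, returning records and the full trace.

    Images whose metadata already records the configured downsampling
    (e.g. synthetic scenes generated at the post-resize geometry) are not
    resized again.
    """
    config = config or PipelineConfig()
    trace = StageTrace()
    t = time.perf_counter

    def tick(name, t0):
        trace.timings_s[name] = time.perf_counter() - t0

    t0 = t()
    if config.downsample_factor % image.downsample_factor == 0:
        remaining = config.downsample_factor // image.downsample_factor
    else:
        raise ValueError("configured downsample_factor is not a multiple of "
                         "the image's current factor")
    img = preprocess.downsample(image, remaining)
    img = preprocess.gamma_correct(img, config.gamma)
    enhanced = preprocess.enhance_contrast(img, config.se_radius, config.boost)
    trace.enhanced = enhanced.pixels
    tick("preprocess", t0)

    t0 = t()
    varmap = segmentation.variance_transform(enhanced, config.variance_window,
                                             sample=config.sample_variance)
    mask = segmentation.binarize(varmap, config.variance_threshold)
    mask = segmentation.remove_small_objects(mask, config.min_area_px)
    mask = segmentation.fill_small_holes(mask, config.max_hole_diameter_px)
    trace.variance_map, trace.binary_mask = varmap, mask
    trace.cleaned_mask = mask
    tick("segmentation", t0)

    t0 = t()
    distmap = floc.euclidean_distance_map(mask)
    floc_mask = floc.extract_floc_mask(distmap, config.distance_threshold,
                                       config.floc_dilation_radius)
    thin = floc.remove_flocs(mask, floc_mask)
    thin = segmentation.remove_small_objects(thin, config.min_area_px)
    trace.floc_mask, trace.thin_mask = floc_mask, thin
    tick("floc_removal", t0)

    t0 = t()
    skeletons = spine_mod.skeletonize(thin)
    spines = []
    for skel in skeletons:
        spines.extend(spine_mod.extract_all_spines(skel, config.min_filament_len_px))
    trace.skeletons, trace.spines = skeletons, spines
    tick("spine_extraction", t0)

    t0 = t()
    scale = ScaleParams(pixel_pitch_um=image.pixel_pitch_um,
                        magnification=image.magnification,
                        downsample_factor=config.downsample_factor)
    records = classify.filter_by_rrg(spines, config.rrg_threshold, scale,
                                     image_id=image.image_id)
    trace.records = records
    tick("classification", t0)
    return records, trace


def detection_mask(records: list[FilamentRecord], shape) -> np.ndarray:
    """Boolean mask of all accepted spine pixels (the detection output)."""
    mask = np.zeros(shape, bool)
    for rec in records:
        for r, c in rec.spine.path:
            if 0 <= r < shape[0] and 0 <= c < shape[1]:
                mask[r, c] = True
    return mask


def process_batch(paths, config: PipelineConfig | None = None) -> BatchSummary:
    """Process a batch of image files; unreadable files are skipped.

    Returns per-image records and TEFLs plus their mean, the online batch
    statistic (ISM-oTEFL).
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("empty batch")
    config = config or PipelineConfig()
    all_records: list[FilamentRecord] = []
    per_image: dict[str, float] = {}
    ids, skipped = [], []
    for p in paths:
        try:
            img = load_gray_image(p)
        except Exception as exc:  # unreadable file: skip, report
            logger.warning("skipping %s: %s", p, exc)
            skipped.append(str(p))
            continue
        records, _ = process_image(img, config)
        all_records.extend(records)
        per_image[img.image_id] = tefl(records, per_image=True)
        ids.append(img.image_id)
        logger.info("%s: %d filaments, TEFL %.1f um", img.image_id,
                    len(records), per_image[img.image_id])
    if not ids:
        raise IOError("no readable images in batch")
    otefl = float(np.mean([per_image[i] for i in ids]))
    return BatchSummary(image_ids=ids, records=all_records,
                        per_image_tefl_um=per_image, otefl_um=otefl,
                        skipped=skipped)
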