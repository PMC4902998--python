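"""Detection-rate evaluation: consensus ground truth, tolerant pixel
matching, and the three-parameter ROC grid with convex-hull selection.

Positives are the reference filament pixels.  Because background and
non-filament objects vastly outnumber filament pixels, the usual FP/N
rate would be misleadingly tiny; the false-positive rate is therefore
deliberately normalised by the positives as well (FPR = FP/P, so it can
exceed 1), and specificity is its complement.

Matching tolerates small spatial displacement between a marked and a
detected filament: true positives are reference pixels covered by the
disc-dilated detection, false positives are detected pixels not covered
by the disc-dilated reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .floc import dilate_by_radius

__all__ = [
    "EvalCounts",
    "ROCPoint",
    "consensus_mask",
    "match_detection",
    "rates",
    "roc_grid",
    "convex_hull_points",
]


@dataclass
class EvalCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.fp + self.tn

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp,
                          self.fn + other.fn, self.tn + other.tn)


@dataclass
class ROCPoint:
    """One threshold triple with its pooled detection rates."""

    variance_threshold: float
    distance_threshold: float
    rrg_threshold: float
    tpr: float
    fpr: float
    specificity: float
    per_image: list[tuple[float, float]] = field(default_factory=list)


def _as_bool(mask) -> np.ndarray:
    for attr in ("values", "pixels"):
        if hasattr(mask, attr):
            mask = getattr(mask, attr)
    return np.asarray(mask, bool)


def consensus_mask(annotator_masks, min_votes: int = 3) -> np.ndarray:
    """Pixels marked by at least ``min_votes`` annotators are positive."""
    masks = [_as_bool(m) for m in annotator_masks]
    if len(masks) < min_votes:
        raise ValueError("fewer masks than required votes")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("annotator masks must share one shape")
    votes = np.sum(masks, axis=0)
    return votes >= min_votes


def match_detection(reference, detected, dilation_radius: float = 3) -> EvalCounts:
    """Displacement-tolerant pixel matching between reference and detection.

    TP: reference pixels covered by the dilated detection; FN: the rest of
    the reference.  FP: detected pixels not covered by the dilated
    reference.  TN: all remaining pixels.  Radius 0 reduces to exact
    pixelwise agreement.
    """
    ref, det = _as_bool(reference), _as_bool(detected)
    if ref.shape != det.shape:
        raise ValueError("reference and detection shapes differ")
    if dilation_radius < 0:
        raise ValueError("dilation_radius must be >= 0")
    det_dil = dilate_by_radius(det, dilation_radius)
    ref_dil = dilate_by_radius(ref, dilation_radius)
    tp = int(np.count_nonzero(ref & det_dil))
    fn = int(np.count_nonzero(ref & ~det_dil))
    fp = int(np.count_nonzero(det & ~ref_dil))
    tn = ref.size - tp - fn - fp
    return EvalCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def rates(counts: EvalCounts) -> tuple[float, float, float]:
    """(TPR, FPR, specificity) with both rates normalised by the positives."""
    p = counts.p
    if p <= 0:
        raise ZeroDivisionError("no positive pixels; rates undefined")
    tpr = counts.tp / p
    fpr = counts.fp / p
    return tpr, fpr, 1.0 - fpr


def roc_grid(images, references, variance_grid, distance_grid, rrg_grid,
             config=None, dilation_radius: float | None = None) -> list[ROCPoint]:
    """Sweep the full threshold grid, pooling counts across images.

    For every (variance, distance, RRG) triple the complete pipeline runs
    on every image and the detected spine pixels are matched against the
    reference mask.  Intermediate results are cached per image along the
    nesting variance -> distance -> RRG, since the RRG threshold only
    re-filters already-extracted spines.  Per-image (TPR, FPR) pairs are
    kept on each point for dispersion analysis.
    """
    from dataclasses import replace as _replace
    from .io import PipelineConfig
    from .pipeline import process_image, detection_mask

    if not (len(variance_grid) and len(distance_grid) and len(rrg_grid)):
        raise ValueError("threshold grids must be nonempty")
    if len(images) != len(references):
        raise ValueError("one reference mask per image required")
    config = config or PipelineConfig()
    if dilation_radius is None:
        dilation_radius = config.eval_dilation_radius_px
    refs = [_as_bool(r) for r in references]

    points: list[ROCPoint] = []
    for v in variance_grid:
        for d in distance_grid:
            cfg = _replace(config, variance_threshold=float(v),
                           distance_threshold=float(d),
                           rrg_threshold=min(float(r) for r in rrg_grid))
            per_image_records = []
            for img in images:
                recs, _ = process_image(img, cfg)
                per_image_records.append(recs)
            for rt in rrg_grid:
                pooled = EvalCounts(0, 0, 0, 0)
                per_img_rates = []
                for img, recs, ref in zip(images, per_image_records, refs):
                    kept = [r for r in recs if r.rrg >= float(rt)]
                    det = detection_mask(kept, ref.shape)
                    counts = match_detection(ref, det, dilation_radius)
                    pooled = pooled + counts
                    if counts.p > 0:
                        tpr_i, fpr_i, _ = rates(counts)
                        per_img_rates.append((tpr_i, fpr_i))
                tpr, fpr, spec = rates(pooled)
                points.append(ROCPoint(float(v), float(d), float(rt),
                                       tpr, fpr, spec, per_img_rates))
    return points


def convex_hull_points(points: list[ROCPoint], tol: float = 1e-9) -> list[ROCPoint]:
    """Upper-left convex hull in (FPR, TPR) space.

    Dominated points (another point with TPR at least as high and FPR at
    least as low, one strictly) are removed first; the survivors are
    reduced to the concave upper envelope, keeping collinear frontier
    points.  Returned in order of increasing FPR.
    """
    if not points:
        raise ValueError("need at least one ROC point")
    def dominates(q: ROCPoint, p: ROCPoint) -> bool:
        return (q.tpr >= p.tpr - tol and q.fpr <= p.fpr + tol
                and (q.tpr > p.tpr + tol or q.fpr < p.fpr - tol))

    nondom = [p for p in points
              if not any(dominates(q, p) for q in points if q is not p)]
    nondom.sort(key=lambda p: (p.fpr, -p.tpr))
    # monotone-chain upper hull over (fpr, tpr); collinear points retained
    hull: list[ROCPoint] = []
    for p in nondom:
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (a.fpr - o.fpr) * (p.tpr - o.tpr) - (a.tpr - o.tpr) * (p.fpr - o.fpr)
            if cross > tol:  # a lies below the o-p chord: not on the hull
                hull.pop()
            else:
                break
        hull.append(p)
    return hull
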