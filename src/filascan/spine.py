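"""Skeletonization and geodesic spine pruning.

A filament's length must be measured along its medial axis, but thinning
leaves spurious side branches.  The spine is defined as the shortest path
between the two most distant endpoints of a skeleton (the strongest
geodesic ends, SGE), with distances measured along the skeleton using the
quasi-euclidean metric: cost 1 per axial step, sqrt(2) per diagonal step.

The spine pixels are recovered with a sum-map argument: assign every
skeleton pixel the sum of its geodesic distances to both SGE.  Pixels on
the spine all carry the same sum — exactly the geodesic length between the
two ends — while branch pixels carry larger sums, so the spine is the
regional minimum of the sum map.

Residual branches longer than the minimum expected filament length are
reprocessed with the same procedure, which resolves crossing filaments
('X' configurations) into multiple spines.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

__all__ = [
    "SkeletonComponent",
    "Spine",
    "skeletonize",
    "find_endpoint_candidates",
    "geodesic_distance",
    "find_sge",
    "extract_spine",
    "reprocess_branches",
    "extract_all_spines",
]

_SQRT2 = math.sqrt(2.0)
# 8-neighbourhood offsets with their quasi-euclidean step costs
_STEPS = [(-1, -1, _SQRT2), (-1, 0, 1.0), (-1, 1, _SQRT2),
          (0, -1, 1.0), (0, 1, 1.0),
          (1, -1, _SQRT2), (1, 0, 1.0), (1, 1, _SQRT2)]


@dataclass
class SkeletonComponent:
    """One 8-connected, one-pixel-wide skeleton inside its bounding frame."""

    frame: np.ndarray  # bool, cropped to the component's bounding box
    frame_offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, bool)

    @property
    def pixels(self) -> np.ndarray:
        """(N, 2) array of (row, col) coordinates local to the frame."""
        return np.argwhere(self.frame)

    def global_pixels(self) -> np.ndarray:
        return self.pixels + np.asarray(self.frame_offset)

    def neighbor_counts(self) -> np.ndarray:
        k = np.ones((3, 3), dtype=int)
        k[1, 1] = 0
        counts = ndimage.convolve(self.frame.astype(int), k, mode="constant")
        return np.where(self.frame, counts, -1)

    def endpoints(self) -> list[tuple[int, int]]:
        """Skeleton pixels with exactly one 8-neighbour, row-major order."""
        counts = self.neighbor_counts()
        return [tuple(p) for p in np.argwhere(counts == 1)]


@dataclass
class Spine:
    """Ordered path of skeleton pixels with its quasi-euclidean length.

    ``path`` holds global (row, col) image coordinates ordered by geodesic
    distance from one strongest geodesic end; ``closed`` marks loop
    skeletons whose length is the full cycle perimeter.
    """

    path: list[tuple[int, int]]
    geodesic_length_px: float
    closed: bool = False

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        return set(self.path)


def skeletonize(mask) -> list[SkeletonComponent]:
    """Topology-preserving thinning, one skeleton per 8-connected object.

    Each object is recovered in the smallest rectangular frame containing
    it before thinning, so downstream geodesic processing works on small
    crops.
    """
    mask = np.asarray(mask.values if hasattr(mask, "values") else mask, bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    comps: list[SkeletonComponent] = []
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        crop = labels[sl] == lab
        # pad by 1 so thinning sees a background ring, then crop back
        skel = morphology.skeletonize(np.pad(crop, 1))[1:-1, 1:-1]
        if not skel.any():
            # tiny objects can thin to nothing; keep their densest pixel
            skel = np.zeros_like(crop)
            r, c = np.argwhere(crop)[0]
            skel[r, c] = True
        comps.append(SkeletonComponent(skel, (sl[0].start, sl[1].start)))
    return comps


def find_endpoint_candidates(skel: SkeletonComponent) -> list[tuple[int, int]]:
    """Preselect up to four endpoints, one nearest to each frame border.

    For each border (top, bottom, left, right) the endpoint with minimal
    distance to that border is chosen; ties go to the smaller row-major
    pixel index (closest to the upper-left corner).  Duplicates collapse,
    so a simple arc yields just its two ends.
    """
    eps = skel.endpoints()
    if not eps:
        raise ValueError("skeleton has no endpoints (closed loop)")
    h, w = skel.frame.shape

    def border_dist(p, border):
        r, c = p
        return {"top": r, "bottom": h - 1 - r, "left": c, "right": w - 1 - c}[border]

    chosen: list[tuple[int, int]] = []
    for border in ("top", "bottom", "left", "right"):
        best = min(eps, key=lambda p: (border_dist(p, border), p[0] * w + p[1]))
        if best not in chosen:
            chosen.append(best)
    return chosen


def _dijkstra(frame: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
    """Quasi-euclidean shortest-path distances along the skeleton pixels."""
    h, w = frame.shape
    dist = np.full((h, w), np.inf)
    r0, c0 = origin
    if not (0 <= r0 < h and 0 <= c0 < w) or not frame[r0, c0]:
        raise ValueError("origin is not a skeleton pixel")
    dist[r0, c0] = 0.0
    heap = [(0.0, r0, c0)]
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc, cost in _STEPS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and frame[rr, cc]:
                nd = d + cost
                if nd < dist[rr, cc] - 1e-12:
                    dist[rr, cc] = nd
                    heapq.heappush(heap, (nd, rr, cc))
    return dist


def geodesic_distance(skel: SkeletonComponent, origin: tuple[int, int]) -> np.ndarray:
    """Geodesic distance map from ``origin`` restricted to skeleton pixels.

    Returns a frame-shaped array; non-skeleton pixels and unreachable
    pixels hold +inf.  Origin is in local frame coordinates.
    """
    return _dijkstra(skel.frame, tuple(origin))


def find_sge(skel: SkeletonComponent,
             candidates: list[tuple[int, int]]) -> tuple[tuple[int, int], tuple[int, int], float]:
    """Find the strongest geodesic ends among the candidate endpoints.

    For each candidate the full geodesic map is computed; the candidate /
    argmax-pixel pair with the overall largest distance wins.  Ties are
    broken by the row-major index of the first end, then of the second.
    """
    if not candidates:
        raise ValueError("need at least one candidate endpoint")
    w = skel.frame.shape[1]
    best: tuple[float, int, int] | None = None
    best_pair = None
    for cand in candidates:
        dmap = geodesic_distance(skel, cand)
        finite = np.where(np.isfinite(dmap), dmap, -1.0)
        dmax = finite.max()
        # all argmax pixels, smallest row-major index first
        rows, cols = np.nonzero(finite >= dmax - 1e-9)
        idx = rows * w + cols
        far = (rows[idx.argmin()], cols[idx.argmin()])
        key = (-dmax, cand[0] * w + cand[1], far[0] * w + far[1])
        if best is None or key < best:
            best = key
            best_pair = (tuple(cand), (int(far[0]), int(far[1])), float(dmax))
    return best_pair


def extract_spine(skel: SkeletonComponent, end_a: tuple[int, int],
                  end_b: tuple[int, int], *, tol: float | None = None) -> Spine:
    """Isolate the spine between two ends by the sum-map regional minimum.

    The sum of the geodesic maps from both ends equals the a-b geodesic
    length exactly on the spine and exceeds it on branches; pixels within
    ``tol`` of the minimum are kept and ordered by distance from
    ``end_a``.  ``tol`` defaults to 1e-6 times the frame diagonal,
    absorbing floating-point drift.
    """
    da = geodesic_distance(skel, end_a)
    db = geodesic_distance(skel, end_b)
    total = da + db
    length = float(da[end_b])
    if not math.isfinite(length):
        raise ValueError("end_b unreachable from end_a")
    h, w = skel.frame.shape
    if tol is None:
        tol = 1e-6 * math.hypot(h, w)
    on_spine = np.isfinite(total) & (total <= length + tol)
    rows, cols = np.nonzero(on_spine)
    order = np.lexsort((rows * w + cols, da[rows, cols]))
    off_r, off_c = skel.frame_offset
    path = [(int(rows[i]) + off_r, int(cols[i]) + off_c) for i in order]
    return Spine(path=path, geodesic_length_px=length)


def _loop_spine(skel: SkeletonComponent) -> Spine:
    """Closed skeleton with no endpoints: keep the whole loop as one spine.

    The length is the cycle perimeter (sum of quasi-euclidean steps around
    the loop, including the closing step) when the component is a simple
    cycle; otherwise the pixel nearest the upper-left corner serves as a
    pseudo-endpoint and the normal SGE procedure applies.
    """
    counts = skel.neighbor_counts()
    pix = skel.pixels
    off_r, off_c = skel.frame_offset
    if np.all(counts[pix[:, 0], pix[:, 1]] == 2) and len(pix) >= 3:
        # simple cycle: walk it
        start = tuple(pix[np.lexsort((pix[:, 1], pix[:, 0]))[0]])
        path = [start]
        visited = {start}
        length = 0.0
        cur = start
        while True:
            nxt = None
            for dr, dc, cost in _STEPS:
                cand = (cur[0] + dr, cur[1] + dc)
                if (0 <= cand[0] < skel.frame.shape[0]
                        and 0 <= cand[1] < skel.frame.shape[1]
                        and skel.frame[cand] and cand not in visited):
                    nxt = (cand, cost)
                    break
            if nxt is None:
                break
            cur = nxt[0]
            visited.add(cur)
            path.append(cur)
            length += nxt[1]
        dr, dc = abs(cur[0] - start[0]), abs(cur[1] - start[1])
        length += _SQRT2 if (dr and dc) else 1.0  # closing step
        gpath = [(r + off_r, c + off_c) for r, c in path]
        return Spine(path=gpath, geodesic_length_px=length, closed=True)
    # loop with junctions: fall back to a pseudo-endpoint
    w = skel.frame.shape[1]
    pseudo = tuple(pix[np.argmin(pix[:, 0] * w + pix[:, 1])])
    end_a, end_b, _ = find_sge(skel, [pseudo])
    return extract_spine(skel, end_a, end_b)


def reprocess_branches(skel: SkeletonComponent, spine: Spine,
                       min_len_px: float = 31) -> list[Spine]:
    """Recursively extract supplementary spines from long residual branches.

    The spine pixels are removed from the skeleton; every residual
    8-connected component whose geodesic extent exceeds ``min_len_px``
    (the minimum expected filament length) is run through the same
    endpoint-candidate / SGE / spine procedure, recursively.  Crossing
    filaments are thereby split into their constituent spines.
    """
    off_r, off_c = skel.frame_offset
    residual = skel.frame.copy()
    for r, c in spine.path:
        residual[r - off_r, c - off_c] = False
    out: list[Spine] = []
    labels, n = ndimage.label(residual, structure=np.ones((3, 3), int))
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        sub = SkeletonComponent(labels[sl] == lab,
                                (off_r + sl[0].start, off_c + sl[1].start))
        try:
            cands = find_endpoint_candidates(sub)
        except ValueError:
            sub_spine = _loop_spine(sub)
            if sub_spine.geodesic_length_px > min_len_px:
                out.append(sub_spine)
            continue
        end_a, end_b, dmax = find_sge(sub, cands)
        if dmax > min_len_px:
            sub_spine = extract_spine(sub, end_a, end_b)
            out.append(sub_spine)
            out.extend(reprocess_branches(sub, sub_spine, min_len_px))
    return out


def extract_all_spines(skel: SkeletonComponent,
                       min_len_px: float = 31) -> list[Spine]:
    """Primary spine plus recursively reprocessed branch spines."""
    try:
        cands = find_endpoint_candidates(skel)
    except ValueError:
        return [_loop_spine(skel)]
    end_a, end_b, _ = find_sge(skel, cands)
    primary = extract_spine(skel, end_a, end_b)
    return [primary] + reprocess_branches(skel, primary, min_len_px)
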