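"""Synthetic micrograph scenes with exact ground truth.

Emulates bright-field in-situ micrographs of activated sludge at the
post-resize geometry (default 520 x 696 px, where one pixel spans
0.3225 um of object space): thin dark curvilinear filaments of width
2.5-5 px and length 31-620 px, large grainy flocs, small debris specks,
strongly blurred out-of-focus objects, and additive sensor noise on a
mid-grey background, quantized to 8 bits.

Filament centrelines are integrated bounded-curvature headings — smooth
curves with few direction changes, like the organisms themselves — and
every scene carries its exact ground truth: per-filament spine pixel
chains with their quasi-euclidean geodesic lengths, the filament and floc
masks, and in/out-of-focus labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import polygon as draw_polygon

from .io import GrayImage

__all__ = ["SceneSpec", "GroundTruth", "GenerationError",
           "generate_scene", "scenario_suite", "chain_length"]

_SQRT2 = math.sqrt(2.0)
_STEP = 0.25  # centreline sampling interval, px


class GenerationError(RuntimeError):
    """Raised when objects cannot be packed into the frame."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene; a single seed drives everything."""

    image_size: tuple[int, int] = (520, 696)
    n_filaments: int = 5
    filament_length_px_range: tuple[float, float] = (31.0, 620.0)
    filament_width_px_range: tuple[float, float] = (2.5, 5.0)
    filament_contrast: float = -0.35  # negative: dark in-focus objects
    n_flocs: int = 2
    floc_radius_px_range: tuple[float, float] = (15.0, 60.0)
    n_blurred_objects: int = 0
    blur_sigma_px: float = 5.0
    n_debris: int = 8
    noise_sigma: float = 0.004
    background_level: float = 0.6
    seed: int = 0
    # filament centrelines: heading noise per px (elongated organisms with
    # few directional changes -> small curvature)
    curvature_sigma: float = 0.015
    # scene-construction switches used by the scenario battery
    min_separation_px: float = 0.0
    crossing_pairs: int = 0
    attach_to_flocs: bool = False


@dataclass
class GroundTruth:
    """Exact per-scene truth: masks, spine chains and focus labels."""

    filament_mask: np.ndarray
    floc_mask: np.ndarray
    spines: list[tuple[list[tuple[int, int]], float]]
    labels: list[str] = field(default_factory=list)


def chain_length(path) -> float:
    """Quasi-euclidean length of an 8-connected pixel chain."""
    total = 0.0
    for (r0, c0), (r1, c1) in zip(path[:-1], path[1:]):
        total += _SQRT2 if (r0 != r1 and c0 != c1) else 1.0
    return total


def _steer(heading: float, pos: np.ndarray, shape, margin: float) -> float:
    """Gently bend the heading toward the frame centre near a border.

    The turn rate is capped so that border avoidance never produces the
    tight self-loops real filaments do not exhibit.
    """
    h, w = shape
    r, c = pos
    if not (r < margin or r > h - 1 - margin or c < margin or c > w - 1 - margin):
        return heading
    target = math.atan2(h / 2 - r, w / 2 - c)
    diff = (target - heading + math.pi) % (2 * math.pi) - math.pi
    return heading + np.clip(diff, -0.02, 0.02)


def _curve(rng, start, heading, length, shape, curvature_sigma=0.015) -> np.ndarray:
    """Integrate a bounded-curvature heading into a dense centreline."""
    pts = [np.asarray(start, float)]
    pos = np.asarray(start, float).copy()
    n_steps = int(math.ceil(length / _STEP))
    drift = 0.0
    for _ in range(n_steps):
        drift = 0.9 * drift + rng.normal(0.0, curvature_sigma)
        heading = _steer(heading + drift * _STEP, pos, shape, margin=25.0)
        pos = pos + _STEP * np.array([math.sin(heading), math.cos(heading)])
        pos[0] = np.clip(pos[0], 1.0, shape[0] - 2.0)
        pos[1] = np.clip(pos[1], 1.0, shape[1] - 2.0)
        pts.append(pos.copy())
    return np.array(pts)


def _curve_through(rng, point, heading, length, shape,
                   curvature_sigma=0.015) -> np.ndarray:
    """Centreline of given length passing through ``point``."""
    half_a = _curve(rng, point, heading, length / 2, shape, curvature_sigma)
    half_b = _curve(rng, point, heading + math.pi, length / 2, shape,
                    curvature_sigma)
    return np.vstack([half_b[::-1], half_a[1:]])


def _chain_from_points(points: np.ndarray) -> list[tuple[int, int]]:
    """Rasterize a dense centreline into an 8-connected pixel chain.

    Anchors are taken every ~2 px along the curve and joined by Bresenham
    segments, which yields minimal monotone staircases; naive per-sample
    rounding would zigzag across rows lying near half-integer coordinates
    and inflate the chain's geodesic length.
    """
    from skimage.draw import line as draw_line

    stride = max(int(round(2.0 / _STEP)), 1)
    anchors = np.round(points[::stride]).astype(int)
    if not np.array_equal(anchors[-1], np.round(points[-1]).astype(int)):
        anchors = np.vstack([anchors, np.round(points[-1]).astype(int)])
    chain: list[tuple[int, int]] = []
    for (r0, c0), (r1, c1) in zip(anchors[:-1], anchors[1:]):
        rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
        for p in zip(rr.tolist(), cc.tolist()):
            if chain and p == chain[-1]:
                continue
            chain.append(p)
    if not chain:
        chain = [tuple(np.round(points[0]).astype(int))]
    return chain


def _tube_alpha(points: np.ndarray, width: float, shape) -> np.ndarray:
    """Anti-aliased tube of the given width around a dense centreline.

    Pixel coverage is approximated from the continuous distance to the
    sampled centreline (cKDTree nearest-point query on a local window).
    """
    h, w = shape
    pad = width / 2 + 2.0
    r0 = max(int(points[:, 0].min() - pad), 0)
    r1 = min(int(points[:, 0].max() + pad) + 1, h)
    c0 = max(int(points[:, 1].min() - pad), 0)
    c1 = min(int(points[:, 1].max() + pad) + 1, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    tree = cKDTree(points)
    d, _ = tree.query(np.column_stack([rr.ravel(), cc.ravel()]),
                      distance_upper_bound=pad)
    d = d.reshape(rr.shape)
    alpha = np.zeros(shape)
    alpha[r0:r1, c0:c1] = np.clip(width / 2 + 0.5 - d, 0.0, 1.0)
    return alpha


def _self_approach(points: np.ndarray, radius: float) -> bool:
    """True when the centreline comes back within ``radius`` of itself.

    Pairs of samples closer than ``radius`` in space but far apart along
    the arc indicate a self-crossing or near-loop.
    """
    tree = cKDTree(points)
    arc_gap = int(3.0 * radius / _STEP)
    return any(abs(i - j) > arc_gap for i, j in tree.query_pairs(radius))


def _floc_shape(rng, shape, radius_range, center=None) -> np.ndarray:
    """Irregular blob mask: a disc with low-order radial perturbations."""
    h, w = shape
    r0 = rng.uniform(*radius_range)
    if center is None:
        center = (rng.uniform(r0, h - r0), rng.uniform(r0, w - r0))
    theta = np.linspace(0, 2 * math.pi, 120, endpoint=False)
    radial = np.ones_like(theta)
    for k in range(2, 6):
        radial += rng.normal(0, 0.08) * np.cos(k * theta + rng.uniform(0, 2 * math.pi))
    radial = np.clip(radial, 0.5, 1.5) * r0
    rr = center[0] + radial * np.sin(theta)
    cc = center[1] + radial * np.cos(theta)
    mask = np.zeros(shape, bool)
    pr, pc = draw_polygon(np.clip(rr, 0, h - 1), np.clip(cc, 0, w - 1), shape)
    mask[pr, pc] = True
    return mask


def generate_scene(spec: SceneSpec) -> tuple[GrayImage, GroundTruth]:
    """Render one scene and its exact ground truth; same seed, same scene."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_size
    h, w = shape
    img = np.full(shape, spec.background_level)

    # --- flocs: dark grainy aggregates -------------------------------------
    floc_mask = np.zeros(shape, bool)
    for _ in range(spec.n_flocs):
        floc_mask |= _floc_shape(rng, shape, spec.floc_radius_px_range)
    if spec.n_flocs:
        alpha = ndimage.gaussian_filter(floc_mask.astype(float), 1.0)
        texture = ndimage.gaussian_filter(rng.normal(size=shape), 0.7)
        texture *= 0.08 / max(texture.std(), 1e-12)
        img = img - alpha * (0.25 + texture)

    # --- in-focus filaments -------------------------------------------------
    filament_mask = np.zeros(shape, bool)
    spines: list[tuple[list[tuple[int, int]], float]] = []
    labels: list[str] = []
    occupied = np.zeros(shape, bool)

    def sample_start():
        if spec.attach_to_flocs and floc_mask.any():
            boundary = floc_mask & ~ndimage.binary_erosion(floc_mask, iterations=3)
            cand = np.argwhere(boundary)
            return cand[rng.integers(len(cand))].astype(float)
        m = 12.0
        return np.array([rng.uniform(m, h - m), rng.uniform(m, w - m)])

    n_crossing = 2 * spec.crossing_pairs
    for i in range(spec.n_filaments):
        placed = False
        for _ in range(100):
            length = rng.uniform(*spec.filament_length_px_range)
            width = rng.uniform(*spec.filament_width_px_range)
            if i < n_crossing and i % 2 == 1 and spines:
                # cross the previous filament near its midpoint
                prev = spines[-1][0]
                pivot = np.asarray(prev[len(prev) // 2], float)
                heading = rng.uniform(0, 2 * math.pi)
                pts = _curve_through(rng, pivot, heading, length, shape,
                                     spec.curvature_sigma)
            else:
                pts = _curve(rng, sample_start(), rng.uniform(0, 2 * math.pi),
                             length, shape, spec.curvature_sigma)
            if spec.min_separation_px > 0 and _self_approach(pts, spec.min_separation_px):
                continue
            alpha = _tube_alpha(pts, width, shape)
            tube = alpha >= 0.5
            if spec.min_separation_px > 0 and occupied.any():
                sep = ndimage.distance_transform_edt(~occupied)
                if sep[tube].min() < spec.min_separation_px:
                    continue
            placed = True
            break
        if not placed:
            raise GenerationError("could not pack filaments under the "
                                  "separation constraint")
        chain = _chain_from_points(pts)
        img = img + np.sign(spec.filament_contrast) * abs(spec.filament_contrast) * alpha
        filament_mask |= tube
        occupied |= tube
        spines.append((chain, chain_length(chain)))
        labels.append("in-focus")

    # --- small debris specks (removed by the size filter downstream) -------
    for _ in range(spec.n_debris):
        r = rng.uniform(4, h - 4)
        c = rng.uniform(4, w - 4)
        rad = rng.uniform(1.0, 2.5)
        pts = np.array([[r, c]])
        img = img - 0.3 * _tube_alpha(pts, 2 * rad, shape)

    # --- out-of-focus objects: strong blur, attenuated, brighter -----------
    for _ in range(spec.n_blurred_objects):
        length = rng.uniform(50, 250)
        width = rng.uniform(3.0, 6.0)
        pts = _curve(rng, sample_start(), rng.uniform(0, 2 * math.pi),
                     length, shape, spec.curvature_sigma)
        alpha = _tube_alpha(pts, width, shape)
        layer = ndimage.gaussian_filter(alpha * 0.25 * abs(spec.filament_contrast),
                                        spec.blur_sigma_px)
        img = img + layer  # off-focus away from the objective: brighter
        labels.append("out-of-focus")

    # --- sensor noise and 8-bit quantization --------------------------------
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=shape)
    img = np.round(np.clip(img, 0.0, 1.0) * 255.0) / 255.0

    gray = GrayImage(img, downsample_factor=2, image_id=f"scene_seed{spec.seed}")
    return gray, GroundTruth(filament_mask=filament_mask, floc_mask=floc_mask,
                             spines=spines, labels=labels)


def scenario_suite(seed: int = 0) -> list[tuple[GrayImage, GroundTruth]]:
    """Fixed five-scene battery covering the difficult configurations.

    Isolated filaments; crossing filaments; filaments touching flocs; high
    floc density; mixed focus.  One scene each, seeded deterministically
    from ``seed``.
    """
    base = SceneSpec(seed=seed)
    specs = [
        replace(base, n_filaments=4, n_flocs=0, n_debris=4,
                min_separation_px=12.0, seed=seed * 10 + 1),
        replace(base, n_filaments=4, n_flocs=0, crossing_pairs=2,
                filament_length_px_range=(80.0, 400.0), seed=seed * 10 + 2),
        replace(base, n_filaments=3, n_flocs=2, attach_to_flocs=True,
                seed=seed * 10 + 3),
        replace(base, n_filaments=2, n_flocs=6,
                floc_radius_px_range=(20.0, 55.0), seed=seed * 10 + 4),
        replace(base, n_filaments=4, n_flocs=0, n_blurred_objects=3,
                seed=seed * 10 + 5),
    ]
    names = ["isolated", "crossing", "floc_touch", "floc_dense", "mixed_focus"]
    out = []
    for name, sp in zip(names, specs):
        img, gt = generate_scene(sp)
        img.image_id = name
        out.append((img, gt))
    return out
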