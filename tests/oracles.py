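"""Independent oracles and fixture builders shared by the test modules."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from filascan.spine import SkeletonComponent

SQRT2 = math.sqrt(2.0)


def skeleton_from_coords(coords, offset=(0, 0)) -> SkeletonComponent:
    """Build a SkeletonComponent from a list of (row, col) pixels."""
    coords = np.asarray(list(coords), int)
    r0, c0 = coords.min(axis=0)
    frame = np.zeros(tuple(coords.max(axis=0) - (r0, c0) + 1), bool)
    frame[coords[:, 0] - r0, coords[:, 1] - c0] = True
    return SkeletonComponent(frame, (offset[0] + int(r0), offset[1] + int(c0)))


def pixel_graph(frame: np.ndarray) -> nx.Graph:
    """Weighted 8-adjacency graph of a pixel set (1 axial, sqrt(2) diagonal)."""
    g = nx.Graph()
    pix = list(map(tuple, np.argwhere(frame)))
    g.add_nodes_from(pix)
    for r, c in pix:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) == (0, 0):
                    continue
                q = (r + dr, c + dc)
                if q in g:
                    g.add_edge((r, c), q, weight=SQRT2 if dr and dc else 1.0)
    return g


def dijkstra_oracle(frame: np.ndarray, origin) -> dict:
    """Reference shortest-path lengths over the pixel graph."""
    return nx.single_source_dijkstra_path_length(pixel_graph(frame), tuple(origin))


def brute_force_edt(mask: np.ndarray) -> np.ndarray:
    """All-pairs nearest-background search; exact but O(n^2)."""
    mask = np.asarray(mask, bool)
    out = np.zeros(mask.shape, float)
    bg = np.argwhere(~mask)
    if len(bg) == 0:
        return np.full(mask.shape, np.inf) * mask
    for r, c in np.argwhere(mask):
        d = np.sqrt(((bg - (r, c)) ** 2).sum(axis=1)).min()
        out[r, c] = d
    return out


def random_connected_pixels(rng: np.random.Generator, n: int,
                            tree: bool = False) -> np.ndarray:
    """Grow a random 8-connected pixel set (optionally a tree in the
    adjacency graph) of about ``n`` pixels inside a 64x64 frame."""
    frame = np.zeros((64, 64), bool)
    start = (32, 32)
    frame[start] = True
    pixels = [start]
    attempts = 0
    while len(pixels) < n and attempts < 40 * n:
        attempts += 1
        r, c = pixels[rng.integers(len(pixels))]
        dr, dc = rng.integers(-1, 2), rng.integers(-1, 2)
        q = (r + dr, c + dc)
        if (dr, dc) == (0, 0) or not (0 <= q[0] < 64 and 0 <= q[1] < 64) or frame[q]:
            continue
        if tree:
            # new pixel may touch only its parent, so the graph stays a tree
            nbrs = 0
            for er in (-1, 0, 1):
                for ec in (-1, 0, 1):
                    if (er, ec) != (0, 0) and 0 <= q[0] + er < 64 and 0 <= q[1] + ec < 64:
                        nbrs += frame[q[0] + er, q[1] + ec]
            if nbrs != 1:
                continue
        frame[q] = True
        pixels.append(q)
    return frame
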