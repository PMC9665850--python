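"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: the Bernsen oracle scans
each pixel's circular neighborhood explicitly, and the labeling oracle is a
plain breadth-first flood fill.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def disk_offsets(radius: int) -> np.ndarray:
    """(dr, dc) offsets with Euclidean distance <= radius, center included."""
    offs = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    return np.array(offs, dtype=int)


def bernsen_oracle(
    img: np.ndarray, radius: int, contrast: float, bit_depth: int = 8
) -> np.ndarray:
    """Per-pixel min/max scan over the border-clipped circular neighborhood."""
    h, w = img.shape
    offs = disk_offsets(radius)
    half = 2 ** (bit_depth - 1)
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            rr = offs[:, 0] + r
            cc = offs[:, 1] + c
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            vals = img[rr[ok], cc[ok]]
            lo, hi = int(vals.min()), int(vals.max())
            mid = (lo + hi) / 2.0
            if hi - lo >= contrast:
                out[r, c] = img[r, c] > mid
            else:
                out[r, c] = mid >= half
    return out


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """BFS labeling in raster-scan seed order; background stays 0."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    labels = np.zeros((h, w), dtype=int)
    nxt = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                nxt += 1
                q = deque([(r0, c0)])
                labels[r0, c0] = nxt
                while q:
                    r, c = q.popleft()
                    for dr, dc in nbrs:
                        nr, nc = r + dr, c + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and labels[nr, nc] == 0:
                            labels[nr, nc] = nxt
                            q.append((nr, nc))
    return labels
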