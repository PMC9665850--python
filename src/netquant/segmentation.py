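"""Connected-component particle analysis.

Labels foreground components, applies the per-objective size gates
(inclusive at both ends, matching ImageJ size-range semantics), and
measures per-object geometry and per-channel cumulative intensity.

Boundary convention: the "circumference" of an object is the ordered list
of its outer-boundary pixels — object pixels with at least one 8-neighbor
in the background (or outside the image) — traced clockwise starting from
the topmost-then-leftmost boundary pixel. Coordinates are 0-based
(row, col), origin at top-left. Objects touching the image border are kept.
"""

from __future__ import annotations

import math

import numpy as np
from skimage import measure as skmeasure

from .errors import DimensionError, ParameterError
from .types import BinaryMask, MultiChannelField, ObjectRecord


def label_components(mask: BinaryMask | np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label maximal connected foreground components.

    Labels are positive integers assigned in raster-scan order of each
    component's first pixel; background is 0.
    """
    raster = mask.raster if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if connectivity not in (4, 8):
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    labels = skmeasure.label(raster, connectivity=1 if connectivity == 4 else 2)
    return _relabel_raster_order(labels)


def _relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Renumber labels by raster-scan order of first occurrence (determinism contract)."""
    flat = labels.ravel()
    ids, first = np.unique(flat, return_index=True)
    nz = ids != 0
    ids, first = ids[nz], first[nz]
    order = np.argsort(first, kind="stable")
    lut = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    lut[ids[order]] = np.arange(1, len(ids) + 1)
    return lut[labels]


def particle_filter(
    labels: np.ndarray, min_area: int, max_area: float = math.inf
) -> np.ndarray:
    """Retain objects with ``min_area <= area <= max_area`` (inclusive).

    Rejected objects are relabeled to background; surviving labels keep
    their original values, so the operation is idempotent.
    """
    if min_area < 1:
        raise ParameterError(f"min_area must be >= 1, got {min_area}")
    if max_area < min_area:
        raise ParameterError("max_area must be >= min_area")
    labels = np.asarray(labels)
    if labels.max() == 0:
        return labels.copy()
    counts = np.bincount(labels.ravel())
    keep = (counts >= min_area) & (counts <= max_area)
    keep[0] = False
    return np.where(keep[labels], labels, 0)


# Clockwise Moore neighborhood in image coordinates (row down, col right),
# starting due west: W, NW, N, NE, E, SE, S, SW.
_MOORE_CW = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Moore-neighbor boundary trace of a single connected object.

    Returns outer-boundary pixels clockwise from the topmost-then-leftmost
    pixel, each pixel listed once (first visit order kept). The trace stops
    when the (current pixel, backtrack pixel) state recurs, which closes the
    contour exactly for 8-connected objects.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if coords.size == 0:
        return []
    # topmost, then leftmost (argwhere is already in raster order)
    start = (int(coords[0][0]), int(coords[0][1]))
    if coords.shape[0] == 1:
        return [start]
    h, w = mask.shape

    def inside(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and bool(mask[r, c])

    # Raster scan guarantees the west neighbor of start is background.
    start_state = (start, (start[0], start[1] - 1))
    cur, back = start_state
    visited: list[tuple[int, int]] = [start]
    seen = {start}
    guard = 8 * int(mask.sum()) + 8
    for _ in range(guard):
        db = _MOORE_CW.index((back[0] - cur[0], back[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            d = (db + k) % 8
            nr, nc = cur[0] + _MOORE_CW[d][0], cur[1] + _MOORE_CW[d][1]
            if inside(nr, nc):
                nxt = (nr, nc)
                break
            back = (nr, nc)  # last background pixel examined
        if nxt is None:  # cannot happen for area > 1, defensive
            break
        cur = nxt
        if (cur, back) == start_state:
            break
        if cur not in seen:
            seen.add(cur)
            visited.append(cur)
    return visited


def measure_objects(
    labels: np.ndarray, field: MultiChannelField
) -> list[ObjectRecord]:
    """Measure area, centroid, boundary and per-channel sums for each label."""
    labels = np.asarray(labels)
    if labels.shape != field.shape:
        raise DimensionError(
            f"label raster {labels.shape} does not match field {field.shape}"
        )
    records: list[ObjectRecord] = []
    dna = field.dna.astype(np.int64)
    marker = field.marker.astype(np.int64)
    for region in skmeasure.regionprops(labels):
        rmin, cmin, rmax, cmax = region.bbox
        local = labels[rmin:rmax, cmin:cmax] == region.label
        boundary = [(r + rmin, c + cmin) for r, c in trace_boundary(local)]
        rr, cc = np.nonzero(local)
        rr, cc = rr + rmin, cc + cmin
        records.append(
            ObjectRecord(
                label=int(region.label),
                area=int(region.area),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                boundary=boundary,
                sum_dna=float(dna[rr, cc].sum()),
                sum_marker=float(marker[rr, cc].sum()),
                field_id=field.field_id,
            )
        )
    records.sort(key=lambda rec: rec.label)
    return records
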