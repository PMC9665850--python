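"""Channel co-occurrence via the Manders overlap coefficient.

For intensity rasters ``a`` and ``b`` over the ROI pixels ``i``::

    R = sum(a_i * b_i) / sqrt(sum(a_i**2) * sum(b_i**2))

R lies in [0, 1] by Cauchy-Schwarz, is symmetric in the channels and
invariant to positive rescaling of either channel. No background
subtraction or channel thresholding is applied; restrict with an explicit
ROI instead.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .errors import DimensionError, UndefinedResultError
from .types import BinaryMask, OverlapResult


def overlap_coefficient(
    ch1: np.ndarray,
    ch2: np.ndarray,
    roi: Optional[BinaryMask | np.ndarray] = None,
    channel_pair: tuple[str, str] = ("ch1", "ch2"),
) -> OverlapResult:
    """Manders overlap coefficient of two channels over an optional ROI."""
    a = np.asarray(ch1, dtype=np.float64)
    b = np.asarray(ch2, dtype=np.float64)
    if a.shape != b.shape:
        raise DimensionError(f"channel shapes differ: {a.shape} vs {b.shape}")
    if roi is not None:
        r = roi.raster if isinstance(roi, BinaryMask) else np.asarray(roi, dtype=bool)
        if r.shape != a.shape:
            raise DimensionError(f"ROI shape {r.shape} does not match channels {a.shape}")
        a, b = a[r], b[r]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size == 0:
        raise UndefinedResultError("ROI contains no pixels")
    ss1 = float(np.dot(a, a))
    ss2 = float(np.dot(b, b))
    if ss1 == 0.0 or ss2 == 0.0:
        raise UndefinedResultError(
            "overlap coefficient undefined: a channel is all zero within the ROI"
        )
    coeff = float(np.dot(a, b) / np.sqrt(ss1 * ss2))
    return OverlapResult(
        coefficient=coeff, n_pixels=int(a.size), channel_pair=channel_pair
    )
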