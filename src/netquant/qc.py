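"""Per-image quality scoring and exclusion.

The quality score of a field is the fraction of the total DNA-stained area
that lies inside objects accepted by the particle filter — i.e. the part of
the image that can be assigned to individual cells or NETs. Images whose
score falls below ``min_quality`` are flagged as excluded; they are never
removed here, exclusion is applied downstream when aggregating.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .errors import DimensionError
from .types import BinaryMask, QualityReport


def quality_score(
    dna_mask: BinaryMask | np.ndarray,
    accepted: np.ndarray,
    field_id: str = "field",
    min_quality: float = 0.5,
) -> QualityReport:
    """Score one field: assigned DNA area / total DNA area.

    ``accepted`` is the size-gated labeling derived from ``dna_mask``.
    A field with zero DNA foreground scores 0 and is flagged degenerate.
    """
    raster = dna_mask.raster if isinstance(dna_mask, BinaryMask) else np.asarray(dna_mask, bool)
    accepted = np.asarray(accepted)
    if raster.shape != accepted.shape:
        raise DimensionError(
            f"mask {raster.shape} and labeling {accepted.shape} differ in shape"
        )
    dna_area = int(raster.sum())
    if dna_area == 0:
        return QualityReport(
            field_id=field_id,
            dna_area=0,
            assigned_area=0,
            score=0.0,
            excluded=0.0 < min_quality,
            min_quality=min_quality,
            degenerate=True,
        )
    assigned = int((raster & (accepted > 0)).sum())
    score = assigned / dna_area
    return QualityReport(
        field_id=field_id,
        dna_area=dna_area,
        assigned_area=assigned,
        score=score,
        excluded=score < min_quality,
        min_quality=min_quality,
    )


def apply_exclusion(
    reports: list[QualityReport], min_quality: float
) -> list[QualityReport]:
    """Re-evaluate the exclusion flag of every report against ``min_quality``."""
    if not 0.0 <= min_quality <= 1.0:
        raise ValueError("min_quality must lie in [0, 1]")
    return [
        replace(r, excluded=r.score < min_quality, min_quality=min_quality)
        for r in reports
    ]
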