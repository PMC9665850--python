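"""Counting, the %NETs statistic, and time-course classification.

Both counting regimes segment the DNA channel with automatic Bernsen
thresholding to obtain total cells; they differ only in how the NET
(marker) channel is segmented:

* ``auto``   — Bernsen local threshold on the marker channel too,
* ``manual`` — a fixed operator-chosen global threshold that excludes the
  weaker staining of resting nuclei.

%NETs per field of view is ``100 * n_net / n_total``. Per-object
classification (resting vs net) combines the per-objective NET area gate
with a cutoff on marker intensity normalized over the whole time-course
series, mirroring how staining intensities are compared across time points.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateNormalizationError,
    StateError,
    UndefinedResultError,
)
from .qc import quality_score
from .segmentation import label_components, measure_objects, particle_filter
from .thresholding import bernsen_threshold, global_threshold
from .types import (
    BinaryMask,
    FieldResult,
    MultiChannelField,
    ObjectRecord,
    QualityReport,
    RunConfig,
)


class CountWarning(UserWarning):
    """Raised when n_net exceeds n_total (channel fragmentation)."""


def _dna_mask(field: MultiChannelField, config: RunConfig) -> BinaryMask:
    return bernsen_threshold(
        field.dna,
        radius=config.bernsen_radius,
        contrast=config.bernsen_contrast,
        bit_depth=field.bit_depth,
        source_channel="dna",
    )


def count_total(
    field: MultiChannelField, config: RunConfig
) -> tuple[int, np.ndarray]:
    """Count total cells on the DNA channel (automatic thresholding, both regimes)."""
    min_total, _, max_area = config.resolved_gates(field.objective)
    mask = _dna_mask(field, config)
    labels = label_components(mask, config.connectivity)
    accepted = particle_filter(labels, min_total, max_area)
    n = int(len(np.unique(accepted)) - (1 if (accepted == 0).any() else 0))
    return n, accepted


def count_nets(
    field: MultiChannelField, config: RunConfig
) -> tuple[int, np.ndarray]:
    """Count NETs on the marker channel under the configured regime."""
    _, min_net, max_area = config.resolved_gates(field.objective)
    if config.mode == "manual":
        if config.manual_threshold_marker is None:
            raise ConfigurationError("manual mode requires manual_threshold_marker")
        mask = global_threshold(
            field.marker, config.manual_threshold_marker, source_channel="marker"
        )
    else:
        mask = bernsen_threshold(
            field.marker,
            radius=config.bernsen_radius,
            contrast=config.bernsen_contrast,
            bit_depth=field.bit_depth,
            source_channel="marker",
        )
    labels = label_components(mask, config.connectivity)
    accepted = particle_filter(labels, min_net, max_area)
    n = int(len(np.unique(accepted)) - (1 if (accepted == 0).any() else 0))
    return n, accepted


def percent_nets(n_net: int, n_total: int) -> float:
    """%NETs = (NETs / Total cells) x 100.

    Undefined when no total cells were counted; such fields must be excluded.
    """
    if n_net < 0 or n_total < 0:
        raise ValueError("counts must be non-negative")
    if n_total == 0:
        raise UndefinedResultError("%NETs undefined for a field with zero total cells")
    return 100.0 * n_net / n_total


def analyze_field(
    field: MultiChannelField, config: RunConfig
) -> tuple[FieldResult, list[ObjectRecord], QualityReport]:
    """Run the full per-field pipeline: counts, %NETs, quality, measurements.

    Object records are measured on the accepted DNA (total-cell) labeling,
    carrying both channels' cumulative intensities for later classification.
    """
    n_total, accepted_total = count_total(field, config)
    n_net, _ = count_nets(field, config)
    qr = quality_score(
        _dna_mask(field, config), accepted_total, field.field_id, config.min_quality
    )
    if n_total > 0:
        pct = percent_nets(n_net, n_total)
        if n_net > n_total:
            warnings.warn(
                f"field {field.field_id}: n_net ({n_net}) exceeds n_total ({n_total}); "
                "%NETs > 100 reported unclamped",
                CountWarning,
                stacklevel=2,
            )
        excluded = qr.excluded
    else:
        pct = float("nan")
        excluded = True
    records = measure_objects(accepted_total, field)
    result = FieldResult(
        field_id=field.field_id,
        time_point_min=field.time_point_min,
        stimulus=field.stimulus,
        method=config.mode,
        n_total=n_total,
        n_net=n_net,
        percent_net=pct,
        quality_score=qr.score,
        excluded=excluded,
    )
    return result, records, qr


def normalize_timecourse(records: list[ObjectRecord]) -> list[ObjectRecord]:
    """Normalize per-object mean marker intensity over a whole series.

    Every object's mean marker intensity (sum_marker / area) is divided by
    the maximum per-object mean over ALL fields and time points of the
    series, so values fall in (0, 1] with at least one object at exactly 1.
    """
    if not records:
        return []
    means = np.array([r.mean_marker for r in records], dtype=float)
    peak = means.max()
    if peak <= 0:
        raise DegenerateNormalizationError(
            "series carries no marker signal; normalization undefined"
        )
    return [
        replace(r, norm_marker_intensity=float(m / peak))
        for r, m in zip(records, means)
    ]


def classify_objects(
    records: list[ObjectRecord],
    area_min_net: int,
    intensity_min_net: float = 0.3,
) -> list[ObjectRecord]:
    """Classify objects as ``net`` (area AND normalized intensity at/above
    their gates) or ``resting``. Ties classify as net."""
    out = []
    for r in records:
        if r.norm_marker_intensity is None:
            raise StateError(
                "classify_objects requires normalize_timecourse to have run"
            )
        is_net = r.area >= area_min_net and r.norm_marker_intensity >= intensity_min_net
        out.append(replace(r, classification="net" if is_net else "resting"))
    return out


def aggregate(
    results: list[FieldResult],
    group_by: tuple[str, ...] = ("stimulus", "time_point_min", "method"),
) -> pd.DataFrame:
    """Average %NETs per group over fields of view.

    Excluded fields are dropped first; groups left empty are omitted with a
    warning. Standard deviation is the sample SD (ddof=1), 0 for single-FOV
    groups.
    """
    df = pd.DataFrame([vars(r) for r in results])
    if df.empty:
        return pd.DataFrame(columns=[*group_by, "mean_percent_net", "sd_percent_net", "n_fov"])
    kept = df[~df["excluded"]]
    dropped_groups = set(map(tuple, df[list(group_by)].itertuples(index=False))) - set(
        map(tuple, kept[list(group_by)].itertuples(index=False))
    )
    for g in sorted(dropped_groups):
        warnings.warn(f"group {g}: all fields excluded; omitted", UserWarning, stacklevel=2)
    if kept.empty:
        return pd.DataFrame(columns=[*group_by, "mean_percent_net", "sd_percent_net", "n_fov"])
    out = (
        kept.groupby(list(group_by), sort=True)["percent_net"]
        .agg(mean_percent_net="mean", sd_percent_net=lambda s: s.std(ddof=1), n_fov="count")
        .reset_index()
    )
    out["sd_percent_net"] = out["sd_percent_net"].fillna(0.0)
    return out
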