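"""Reading micrographs and writing result tables.

Input images are single-plane or multi-page grayscale TIFFs, 8- or 16-bit.
Outputs are plain CSV tables (UTF-8, header row, '.' decimal separator)
plus a JSON sidecar holding each object's ordered boundary coordinates,
and a JSON run report.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, DimensionError, FormatError
from .types import SIZE_GATES, FieldResult, MultiChannelField, ObjectRecord

OBJECT_COLUMNS = [
    "label",
    "field_id",
    "area_px",
    "centroid_x",
    "centroid_y",
    "sum_dna",
    "sum_marker",
    "class",
]
FIELD_COLUMNS = [
    "field_id",
    "time_point_min",
    "stimulus",
    "method",
    "n_total",
    "n_net",
    "percent_net",
    "quality_score",
    "excluded",
]


def resolve_size_gates(objective: str) -> tuple[int, int]:
    """Particle-size gates for one objective: (min_area_total, min_area_net).

    10x: (25, 75); 20x: (100, 250) — pixels^2, pure function of objective.
    """
    try:
        return SIZE_GATES[objective]
    except KeyError:
        raise ConfigurationError(
            f"no size gates defined for objective {objective!r}; known: {sorted(SIZE_GATES)}"
        ) from None


def _load_planes(path: str | Path) -> list[np.ndarray]:
    """Read a TIFF as a list of 2-D integer planes (multi-page split in order)."""
    arr = tifffile.imread(path)
    if arr.dtype.kind == "f":
        raise FormatError(f"{path}: float sample format is not supported")
    if arr.ndim == 2:
        planes = [arr]
    elif arr.ndim == 3:
        # Reject RGB/RGBA (trailing sample axis); accept page stacks.
        if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
            raise FormatError(f"{path}: RGB/multi-sample TIFF is not supported")
        planes = list(arr)
    else:
        raise FormatError(f"{path}: unsupported TIFF dimensionality {arr.shape}")
    for p in planes:
        if p.dtype.kind not in ("u", "i"):
            raise FormatError(f"{path}: unsupported sample dtype {p.dtype}")
    return planes


def _bit_depth(arr: np.ndarray) -> int:
    bits = arr.dtype.itemsize * 8
    if bits not in (8, 16):
        raise FormatError(f"unsupported bit depth {bits}; expected 8 or 16")
    return bits


def read_field(
    path_dna: str | Path,
    path_marker: str | Path,
    metadata: dict | None = None,
) -> MultiChannelField:
    """Read one two-channel field from a pair of single-plane TIFFs.

    ``metadata`` may set field_id, time_point_min, stimulus and objective;
    bit depth is inferred from the files.
    """
    fields = read_stack(path_dna, path_marker, metadata)
    if len(fields) != 1:
        raise FormatError(
            f"expected single-plane TIFFs, got {len(fields)} pages; use read_stack"
        )
    return fields[0]


def read_stack(
    path_dna: str | Path,
    path_marker: str | Path,
    metadata: dict | None = None,
) -> list[MultiChannelField]:
    """Read a (possibly multi-page) TIFF pair into per-plane fields.

    Pages are paired in order; multi-page inputs get index-derived field ids.
    """
    metadata = dict(metadata or {})
    dna_planes = _load_planes(path_dna)
    marker_planes = _load_planes(path_marker)
    if len(dna_planes) != len(marker_planes):
        raise DimensionError(
            f"page count mismatch: {len(dna_planes)} dna vs {len(marker_planes)} marker"
        )
    base_id = metadata.pop("field_id", Path(path_dna).stem)
    fields = []
    for i, (d, m) in enumerate(zip(dna_planes, marker_planes)):
        if d.shape != m.shape:
            raise DimensionError(
                f"plane {i}: shape mismatch dna {d.shape} vs marker {m.shape}"
            )
        if _bit_depth(d) != _bit_depth(m):
            raise FormatError("dna and marker planes differ in bit depth")
        fid = base_id if len(dna_planes) == 1 else f"{base_id}_p{i:03d}"
        fields.append(
            MultiChannelField(
                dna=d, marker=m, field_id=fid, bit_depth=_bit_depth(d), **metadata
            )
        )
    return fields


def write_tiff(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(path, image)


def write_object_table(records: list[ObjectRecord], path: str | Path) -> Path:
    """Write per-object CSV plus a JSON boundary sidecar.

    The sidecar (``<path stem>.boundaries.json``) maps ``"field_id:label"``
    to the ordered (row, col) boundary coordinate list. centroid_x is the
    column coordinate, centroid_y the row (image convention, 0-based).
    """
    path = Path(path)
    rows = [
        {
            "label": r.label,
            "field_id": r.field_id,
            "area_px": r.area,
            "centroid_x": r.centroid[1],
            "centroid_y": r.centroid[0],
            "sum_dna": r.sum_dna,
            "sum_marker": r.sum_marker,
            "class": r.classification,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=OBJECT_COLUMNS).to_csv(path, index=False)
    sidecar = path.with_suffix(".boundaries.json")
    payload = {
        f"{r.field_id}:{r.label}": [[int(a), int(b)] for a, b in r.boundary]
        for r in records
    }
    sidecar.write_text(json.dumps(payload, sort_keys=True), encoding="utf-8")
    return path


def read_object_table(path: str | Path) -> list[ObjectRecord]:
    """Round-trip reader for :func:`write_object_table` output."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".boundaries.json")
    boundaries = (
        json.loads(sidecar.read_text(encoding="utf-8")) if sidecar.exists() else {}
    )
    records = []
    for row in df.to_dict("records"):  # "class" is a keyword, itertuples mangles it
        key = f"{row['field_id']}:{row['label']}"
        records.append(
            ObjectRecord(
                label=int(row["label"]),
                area=int(row["area_px"]),
                centroid=(float(row["centroid_y"]), float(row["centroid_x"])),
                boundary=[tuple(p) for p in boundaries.get(key, [])],
                sum_dna=float(row["sum_dna"]),
                sum_marker=float(row["sum_marker"]),
                field_id=str(row["field_id"]),
                classification=str(row["class"]),
            )
        )
    return records


def write_field_table(results: list[FieldResult], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "field_id": r.field_id,
            "time_point_min": r.time_point_min,
            "stimulus": r.stimulus,
            "method": r.method,
            "n_total": r.n_total,
            "n_net": r.n_net,
            "percent_net": r.percent_net,
            "quality_score": r.quality_score,
            "excluded": r.excluded,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=FIELD_COLUMNS).to_csv(path, index=False)
    return path


def read_field_table(path: str | Path) -> list[FieldResult]:
    df = pd.read_csv(path)
    return [
        FieldResult(
            field_id=str(r.field_id),
            time_point_min=float(r.time_point_min),
            stimulus="" if pd.isna(r.stimulus) else str(r.stimulus),
            method=str(r.method),
            n_total=int(r.n_total),
            n_net=int(r.n_net),
            percent_net=float(r.percent_net),
            quality_score=float(r.quality_score),
            excluded=bool(r.excluded),
        )
        for r in df.itertuples(index=False)
    ]


def write_run_report(report: dict, path: str | Path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, float) and math.isinf(o):
            return "inf"
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(report, indent=2, default=_default), encoding="utf-8")
    return path
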