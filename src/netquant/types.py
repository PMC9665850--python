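"""Core domain types.

The pipeline passes small immutable-ish dataclasses between stages:
a :class:`MultiChannelField` in, :class:`ObjectRecord` / :class:`FieldResult`
rows out, with :class:`RunConfig` carrying every tunable parameter so the
run report can record the full resolved configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigurationError, DimensionError, FormatError

#: Particle-size gates (pixels^2) per objective: (min_area_total, min_area_net).
#: Totals gate = "the size of a cell nucleus or bigger"; NET gate = "larger
#: than a resting cell nucleus".
SIZE_GATES: dict[str, tuple[int, int]] = {
    "10x": (25, 75),
    "20x": (100, 250),
}

_INT_KINDS = ("u", "i")


def _validate_raster(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(f"{name} raster must be 2-D, got ndim={arr.ndim}")
    if arr.dtype.kind not in _INT_KINDS:
        raise FormatError(
            f"{name} raster must be an integer intensity raster, got {arr.dtype}"
        )
    return arr


@dataclass
class MultiChannelField:
    """A registered pair of single-plane intensity rasters plus metadata.

    ``dna`` is the total-DNA stain channel (Hoechst in the assay this
    models), ``marker`` the antibody channel used to call NETs.
    """

    dna: np.ndarray
    marker: np.ndarray
    field_id: str = "field"
    time_point_min: float = 0.0
    stimulus: str = ""
    objective: str = "20x"
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.dna = _validate_raster(self.dna, "dna")
        self.marker = _validate_raster(self.marker, "marker")
        if self.dna.shape != self.marker.shape:
            raise DimensionError(
                f"channel shape mismatch: dna {self.dna.shape} vs "
                f"marker {self.marker.shape}"
            )
        if self.objective not in SIZE_GATES:
            raise ConfigurationError(
                f"objective {self.objective!r} has no defined size gates; "
                f"known: {sorted(SIZE_GATES)}"
            )
        if self.bit_depth not in (8, 16):
            raise ConfigurationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.time_point_min < 0:
            raise ConfigurationError("time_point_min must be non-negative")
        top = 2**self.bit_depth - 1
        for name, ch in (("dna", self.dna), ("marker", self.marker)):
            if ch.size and (int(ch.min()) < 0 or int(ch.max()) > top):
                raise FormatError(
                    f"{name} intensities exceed the {self.bit_depth}-bit range [0, {top}]"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.dna.shape


@dataclass
class RunConfig:
    """Resolved analysis parameters.

    ``mode`` selects how the NET (marker) channel is segmented: ``auto``
    uses Bernsen local thresholding, ``manual`` a fixed global cutoff.
    The DNA channel is always segmented automatically in both regimes.
    Area gates default to the per-objective values in :data:`SIZE_GATES`.
    """

    mode: str = "auto"
    bernsen_radius: int = 15
    bernsen_contrast: float = 35.0
    manual_threshold_dna: Optional[float] = None
    manual_threshold_marker: Optional[float] = None
    min_area_total: Optional[int] = None  # None -> resolve from objective
    min_area_net: Optional[int] = None
    max_area: float = math.inf
    min_quality: float = 0.5
    connectivity: int = 8
    intensity_min_net: float = 0.3
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "manual"):
            raise ConfigurationError(f"mode must be 'auto' or 'manual', got {self.mode!r}")
        if self.bernsen_radius < 1:
            raise ConfigurationError("bernsen_radius must be a positive integer")
        if self.bernsen_contrast < 0:
            raise ConfigurationError("bernsen_contrast must be non-negative")
        if self.connectivity not in (4, 8):
            raise ConfigurationError("connectivity must be 4 or 8")
        if not 0.0 <= self.min_quality <= 1.0:
            raise ConfigurationError("min_quality must lie in [0, 1]")
        if self.mode == "manual" and self.manual_threshold_marker is None:
            raise ConfigurationError(
                "manual mode requires manual_threshold_marker to be set"
            )

    def resolved_gates(self, objective: str) -> tuple[int, float, float]:
        """Return (min_area_total, min_area_net, max_area) for one field."""
        from .image_io import resolve_size_gates  # local import: no cycle at module load

        gate_total, gate_net = resolve_size_gates(objective)
        min_total = self.min_area_total if self.min_area_total is not None else gate_total
        min_net = self.min_area_net if self.min_area_net is not None else gate_net
        if min_net < min_total:
            raise ConfigurationError(
                f"min_area_net ({min_net}) must be >= min_area_total ({min_total}): "
                "a NET is larger than a resting cell nucleus"
            )
        return min_total, min_net, self.max_area

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(d["max_area"]):
            d["max_area"] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("max_area") in ("inf", "Infinity", None):
            d["max_area"] = math.inf
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class BinaryMask:
    """Foreground/background raster plus provenance of the thresholding step."""

    raster: np.ndarray
    source_channel: str = "dna"
    method: str = "bernsen"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=bool)
        if self.raster.ndim != 2:
            raise FormatError("mask raster must be 2-D")

    @property
    def foreground_area(self) -> int:
        return int(self.raster.sum())


@dataclass
class ObjectRecord:
    """One segmented particle with geometry and per-channel intensity sums."""

    label: int
    area: int
    centroid: tuple[float, float]
    boundary: list[tuple[int, int]]
    sum_dna: float
    sum_marker: float
    field_id: str = ""
    norm_marker_intensity: Optional[float] = None
    classification: str = "unclassified"

    @property
    def mean_marker(self) -> float:
        return self.sum_marker / self.area

    @property
    def mean_dna(self) -> float:
        return self.sum_dna / self.area


@dataclass
class QualityReport:
    """Per-image quality score: fraction of DNA-stained area assigned to accepted objects."""

    field_id: str
    dna_area: int
    assigned_area: int
    score: float
    excluded: bool
    min_quality: float
    degenerate: bool = False


@dataclass
class FieldResult:
    """Per-field counts and the %NETs statistic under one regime."""

    field_id: str
    time_point_min: float
    stimulus: str
    method: str
    n_total: int
    n_net: int
    percent_net: float
    quality_score: float
    excluded: bool


@dataclass
class OverlapResult:
    """Manders overlap coefficient between two channels over an ROI."""

    coefficient: float
    n_pixels: int
    channel_pair: tuple[str, str]
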