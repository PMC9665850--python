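"""Synthetic two-channel micrograph generator with ground truth.

Emulates the three cell states the quantification pipeline must
discriminate:

* **resting** — small multi-lobed nuclei (area in a band strictly below the
  NET gate and at/above the total-cell gate for the objective);
* **spread** — activated cells whose weakly staining lobulated nucleus
  extends over a NET-sized area, the early-time-point confounder of fully
  automatic counting;
* **net** — large diffuse chromatin blobs (area at least twice the NET
  gate) rendered as Gaussian-blurred super-ellipses with soft edges.

Two antibody staining models set the marker-channel contrast:

* ``d3d9_like`` — only NETs carry marker signal above background (an
  antibody specific for decondensed/NETotic chromatin);
* ``chromatin_like`` — every nucleus is stained, NETs brightest (a
  pan-chromatin antibody that also labels resting and spread nuclei).

Channels are class means plus additive Gaussian noise, clipped to the bit
depth. Objects are placed without overlap by rejection sampling; a fixed
seed makes generation bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, DensityError
from .image_io import resolve_size_gates
from .types import MultiChannelField

CLASSES = ("resting", "spread", "net")

#: Clearance kept between footprints (and to the border), in pixels: covers
#: the NET edge blur (3 sigma = 6 px) on both sides plus 8-connectivity.
_SEPARATION = 14


@dataclass
class StainModel:
    """Per-class channel means for one antibody staining behavior."""

    name: str
    dna_mean: dict[str, float]
    marker_mean: dict[str, float]
    noise_sd: float = 3.0
    background_mean: float = 16.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        for table in (self.dna_mean, self.marker_mean):
            missing = set(CLASSES) - set(table)
            if missing:
                raise ConfigurationError(f"stain model lacks means for {sorted(missing)}")


#: NET-specific antibody: resting/spread marker signal sits at background.
D3D9_LIKE = StainModel(
    name="d3d9_like",
    dna_mean={"resting": 180.0, "spread": 140.0, "net": 170.0},
    marker_mean={"resting": 18.0, "spread": 20.0, "net": 200.0},
)

#: Pan-chromatin antibody: all nuclei stained, NETs brightest.
CHROMATIN_LIKE = StainModel(
    name="chromatin_like",
    dna_mean={"resting": 180.0, "spread": 140.0, "net": 170.0},
    marker_mean={"resting": 200.0, "spread": 150.0, "net": 220.0},
)

_MODELS = {m.name: m for m in (D3D9_LIKE, CHROMATIN_LIKE)}


def get_stain_model(name: str) -> StainModel:
    try:
        return _MODELS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown stain model {name!r}; known: {sorted(_MODELS)}"
        ) from None


@dataclass
class SyntheticTruth:
    """Ground truth for one generated field.

    ``table`` has one row per object (id, class, centroid_row, centroid_col,
    area_px, mean_dna, mean_marker); ``label_map`` assigns each footprint
    pixel its object id (footprints are pairwise disjoint).
    """

    table: pd.DataFrame
    label_map: np.ndarray


def _trim(mask: np.ndarray) -> np.ndarray:
    """Crop a footprint mask to its bounding box."""
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    if not rows.any():
        return mask[:0, :0]
    r0, r1 = np.nonzero(rows)[0][[0, -1]]
    c0, c1 = np.nonzero(cols)[0][[0, -1]]
    return mask[r0 : r1 + 1, c0 : c1 + 1]


def _rasterize_ellipses(params: list[tuple], scale: float) -> np.ndarray:
    """Union of ellipses: each param is (dy, dx, a, b, theta) in unit scale."""
    extent = max(
        abs(dy) + a + abs(dx) + b for dy, dx, a, b, _ in params
    )  # generous envelope
    half = int(np.ceil(extent * scale)) + 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    mask = np.zeros(yy.shape, dtype=bool)
    for dy, dx, a, b, theta in params:
        y = yy - dy * scale
        x = xx - dx * scale
        ct, st = np.cos(theta), np.sin(theta)
        u = (x * ct + y * st) / (a * scale)
        v = (-x * st + y * ct) / (b * scale)
        mask |= u * u + v * v <= 1.0
    return _trim(mask)


def _rasterize_superellipse(a: float, b: float, n: float, scale: float) -> np.ndarray:
    half = int(np.ceil(max(a, b) * scale)) + 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    u = np.abs(xx / (a * scale)) ** n
    v = np.abs(yy / (b * scale)) ** n
    return _trim(u + v <= 1.0)


def _fit_area(raster_fn, target_area: float, lo: float, hi: float) -> np.ndarray | None:
    """Iteratively rescale a shape so its pixel count lands in [lo, hi)."""
    scale = 1.0
    mask = raster_fn(scale)
    for _ in range(12):
        area = int(mask.sum())
        if lo <= area < hi:
            return mask
        if area == 0:
            scale *= 2.0
        else:
            scale *= np.sqrt(target_area / area)
        mask = raster_fn(scale)
    area = int(mask.sum())
    return mask if lo <= area < hi else None


def _lobed_footprint(
    rng: np.random.Generator, band: tuple[float, float], n_lobes: tuple[int, int]
) -> np.ndarray:
    """Multi-lobed nucleus: union of jittered ellipses, area within ``band``."""
    lo, hi = band
    for _ in range(20):
        k = int(rng.integers(n_lobes[0], n_lobes[1] + 1))
        params = [
            (
                rng.uniform(-0.7, 0.7),  # dy
                rng.uniform(-0.7, 0.7),  # dx
                rng.uniform(0.7, 1.3),  # a
                rng.uniform(0.5, 1.0),  # b
                rng.uniform(0.0, np.pi),  # theta
            )
            for _ in range(k)
        ]
        margin = 0.15 * (hi - lo)
        target = rng.uniform(lo + margin, hi - margin)
        mask = _fit_area(lambda s: _rasterize_ellipses(params, s), target, lo, hi)
        if mask is not None:
            return mask
    raise DensityError("could not fit a lobed footprint into the requested area band")


def _net_footprint(rng: np.random.Generator, min_area: float) -> np.ndarray:
    """Large diffuse blob: super-ellipse with area in [2.2, 3.2) x NET gate."""
    lo, hi = 2.2 * min_area, 3.2 * min_area
    for _ in range(20):
        a = 1.0
        b = rng.uniform(0.6, 1.0)
        n = rng.uniform(2.5, 4.0)
        target = rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo))
        mask = _fit_area(lambda s: _rasterize_superellipse(a, b, n, s), target, lo, hi)
        if mask is not None:
            return mask
    raise DensityError("could not fit a NET footprint into the requested area band")


def _place(
    rng: np.random.Generator,
    shape: tuple[int, int],
    footprints: list[np.ndarray],
    retry_cap: int,
) -> list[tuple[int, int]]:
    """Rejection-sample non-overlapping top-left anchors for all footprints.

    Bounding-circle separation of ``_SEPARATION`` pixels keeps masks (and the
    blurred NET edges) from merging under 8-connected labeling.
    """
    h, w = shape
    placed: list[tuple[float, float, float]] = []  # (center_r, center_c, radius)
    anchors: list[tuple[int, int]] = []
    tries = 0
    for fp in footprints:
        fh, fw = fp.shape
        radius = 0.5 * float(np.hypot(fh, fw))
        if fh + 2 * _SEPARATION >= h or fw + 2 * _SEPARATION >= w:
            raise DensityError("footprint does not fit in the field")
        while True:
            tries += 1
            if tries > retry_cap:
                raise DensityError(
                    f"could not place {len(footprints)} objects in {h}x{w} "
                    f"within {retry_cap} tries"
                )
            r0 = int(rng.integers(_SEPARATION, h - fh - _SEPARATION))
            c0 = int(rng.integers(_SEPARATION, w - fw - _SEPARATION))
            cr, cc = r0 + fh / 2.0, c0 + fw / 2.0
            if all(
                np.hypot(cr - pr, cc - pc) >= radius + pradius + _SEPARATION
                for pr, pc, pradius in placed
            ):
                placed.append((cr, cc, radius))
                anchors.append((r0, c0))
                break
    return anchors


def generate_field(
    n_resting: int,
    n_spread: int,
    n_net: int,
    stain: StainModel | str = D3D9_LIKE,
    shape: tuple[int, int] = (512, 512),
    objective: str = "20x",
    seed: int = 0,
    field_id: str = "synthetic",
    time_point_min: float = 0.0,
    stimulus: str = "",
    retry_cap: int = 5000,
) -> tuple[MultiChannelField, SyntheticTruth]:
    """Generate one two-channel field plus its ground truth.

    Resting areas are drawn from [min_area_total, min_area_net), spread from
    [min_area_net, 2*min_area_net), NETs from [2.2, 3.2) x min_area_net, all
    resolved for ``objective``. Deterministic for a fixed seed.
    """
    if isinstance(stain, str):
        stain = get_stain_model(stain)
    min_total, min_net = resolve_size_gates(objective)
    rng = np.random.default_rng(seed)

    specs = (
        [("resting", (float(min_total), float(min_net)), (2, 4))] * n_resting
        + [("spread", (float(min_net), 2.0 * min_net), (3, 5))] * n_spread
        + [("net", None, None)] * n_net
    )
    footprints = []
    for cls, band, lobes in specs:
        if cls == "net":
            footprints.append(_net_footprint(rng, float(min_net)))
        else:
            footprints.append(_lobed_footprint(rng, band, lobes))
    anchors = _place(rng, shape, footprints, retry_cap)

    bg = stain.background_mean
    dna = np.full(shape, bg, dtype=np.float64)
    marker = np.full(shape, bg, dtype=np.float64)
    label_map = np.zeros(shape, dtype=np.int32)
    rows = []
    for oid, ((cls, _, _), fp, (r0, c0)) in enumerate(
        zip(specs, footprints, anchors), start=1
    ):
        fh, fw = fp.shape
        win = (slice(r0, r0 + fh), slice(c0, c0 + fw))
        if cls == "net":
            profile = gaussian_filter(fp.astype(np.float64), sigma=2.0)
        else:
            profile = fp.astype(np.float64)
        dna[win] += (stain.dna_mean[cls] - bg) * profile
        marker[win] += (stain.marker_mean[cls] - bg) * profile
        label_map[win][fp] = oid
        rr, cc = np.nonzero(fp)
        rows.append(
            {
                "id": oid,
                "class": cls,
                "centroid_row": float(rr.mean() + r0),
                "centroid_col": float(cc.mean() + c0),
                "area_px": int(fp.sum()),
            }
        )

    top = 255.0
    dna_img = np.clip(dna + rng.normal(0.0, stain.noise_sd, shape), 0, top)
    marker_img = np.clip(marker + rng.normal(0.0, stain.noise_sd, shape), 0, top)
    dna_img = dna_img.round().astype(np.uint8)
    marker_img = marker_img.round().astype(np.uint8)

    for row in rows:
        inside = label_map == row["id"]
        row["mean_dna"] = float(dna_img[inside].mean())
        row["mean_marker"] = float(marker_img[inside].mean())
    columns = ["id", "class", "centroid_row", "centroid_col", "area_px", "mean_dna", "mean_marker"]
    truth = SyntheticTruth(
        table=pd.DataFrame(rows, columns=columns), label_map=label_map
    )
    field = MultiChannelField(
        dna=dna_img,
        marker=marker_img,
        field_id=field_id,
        time_point_min=time_point_min,
        stimulus=stimulus,
        objective=objective,
        bit_depth=8,
    )
    return field, truth


def d3d9_onset(time_point_min: float) -> float:
    """Fraction of full NET marker signal present at a time point.

    The NET-specific epitope appears only once chromatin decondensation has
    begun: no signal before 120 min, linear rise to full signal at 180 min.
    """
    return float(np.clip((time_point_min - 120.0) / 60.0, 0.0, 1.0))


def generate_timecourse(
    series_spec: list[tuple[float, dict[str, int]]],
    stain: StainModel | str = D3D9_LIKE,
    shape: tuple[int, int] = (512, 512),
    objective: str = "20x",
    seed: int = 0,
    fields_per_timepoint: int = 1,
    stimulus: str = "PMA",
) -> list[tuple[MultiChannelField, SyntheticTruth]]:
    """Generate a stimulation time course.

    ``series_spec`` lists (time_point_min, class mix) pairs, the mix giving
    counts per class, e.g. ``{"resting": 12, "net": 8}``. Under the
    ``d3d9_like`` model the NET marker mean ramps with :func:`d3d9_onset`;
    the pan-chromatin model is time-independent.
    """
    if isinstance(stain, str):
        stain = get_stain_model(stain)
    master = np.random.default_rng(seed)
    out = []
    for t, mix in series_spec:
        for rep in range(fields_per_timepoint):
            child_seed = int(master.integers(0, 2**31 - 1))
            model = stain
            if stain.name == "d3d9_like":
                onset = d3d9_onset(t)
                bg = stain.background_mean
                net_mean = bg + (stain.marker_mean["net"] - bg) * onset
                model = replace(
                    stain, marker_mean={**stain.marker_mean, "net": net_mean}
                )
            field, truth = generate_field(
                n_resting=int(mix.get("resting", 0)),
                n_spread=int(mix.get("spread", 0)),
                n_net=int(mix.get("net", 0)),
                stain=model,
                shape=shape,
                objective=objective,
                seed=child_seed,
                field_id=f"t{int(t):04d}_f{rep:02d}",
                time_point_min=float(t),
                stimulus=stimulus,
            )
            out.append((field, truth))
    return out
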