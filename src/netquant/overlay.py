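"""Classification overlays.

Renders the chosen background channel as a contrast-stretched grayscale
image and paints every object's boundary ("circumference") in its class
color, so the per-object calls can be inspected on the original image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import dilation, disk

from .errors import StateError
from .types import MultiChannelField, ObjectRecord

DEFAULT_COLORS: dict[str, tuple[int, int, int]] = {
    "net": (255, 0, 0),
    "resting": (0, 255, 255),
    "unclassified": (255, 255, 0),
}


@dataclass
class OverlayStyle:
    color_map: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COLORS)
    )
    line_width: int = 1
    background: str = "dna"  # dna | marker | composite


def _stretch(channel: np.ndarray) -> np.ndarray:
    """Linear contrast stretch to uint8 [0, 255]; flat images map to 0."""
    ch = channel.astype(np.float64)
    lo, hi = ch.min(), ch.max()
    if hi == lo:
        return np.zeros(ch.shape, dtype=np.uint8)
    return ((ch - lo) / (hi - lo) * 255.0).round().astype(np.uint8)


def render_overlay(
    field_: MultiChannelField,
    records: list[ObjectRecord],
    style: OverlayStyle | None = None,
) -> np.ndarray:
    """Return an (H, W, 3) uint8 RGB raster with class-colored boundaries."""
    style = style or OverlayStyle()
    if style.background == "composite":
        base = _stretch(
            (field_.dna.astype(np.float64) + field_.marker.astype(np.float64)) / 2.0
        )
    elif style.background == "marker":
        base = _stretch(field_.marker)
    else:
        base = _stretch(field_.dna)
    rgb = np.stack([base, base, base], axis=-1)

    h, w = field_.shape
    for rec in records:
        if not rec.boundary:
            raise StateError(f"object {rec.label} carries no boundary coordinates")
        color = style.color_map.get(
            rec.classification, style.color_map.get("unclassified", (255, 255, 0))
        )
        bmask = np.zeros((h, w), dtype=bool)
        rr = np.array([p[0] for p in rec.boundary])
        cc = np.array([p[1] for p in rec.boundary])
        bmask[rr, cc] = True
        if style.line_width > 1:
            bmask = dilation(bmask, disk(style.line_width - 1))
        rgb[bmask] = color
    return rgb
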