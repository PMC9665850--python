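"""Binarization of intensity rasters.

Two regimes are provided, mirroring the two published NET-counting
workflows: Bernsen local adaptive thresholding (the fully automatic
method) and a fixed global cutoff (the manual method, where the operator
raises the threshold until dim resting nuclei are excluded).

Bernsen's rule, per pixel ``p`` with circular neighborhood ``N(p)`` of
radius ``r`` (disk, center included, clipped at image borders)::

    lo  = min N(p);  hi = max N(p);  mid = (lo + hi) / 2
    if hi - lo >= c:      foreground iff  I(p) > mid
    else (low contrast):  foreground iff  mid >= 2**(bit_depth - 1)

``c`` is the local-contrast threshold ("parameter 1" in the ImageJ
auto-local-threshold dialog; default 35 as used for the published runs).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .errors import FormatError, ParameterError
from .types import BinaryMask


def _check_integer(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise FormatError(f"expected a 2-D raster, got ndim={image.ndim}")
    if image.dtype.kind not in ("u", "i"):
        raise FormatError(f"expected an integer intensity raster, got {image.dtype}")
    return image


def bernsen_threshold(
    image: np.ndarray,
    radius: int = 15,
    contrast: float = 35.0,
    bit_depth: int = 8,
    source_channel: str = "dna",
) -> BinaryMask:
    """Bernsen local adaptive threshold.

    Neighborhoods are clipped at the image border: only in-bounds pixels
    contribute to the local min/max. The low-contrast tie rule compares the
    local midgray against half the full bit-depth scale (128 for 8-bit).

    Parameters
    ----------
    image
        2-D integer raster.
    radius
        Disk radius of the local neighborhood, in pixels (>= 1).
    contrast
        Local-contrast threshold ``c`` in intensity units (>= 0). ``c = 0``
        sends every pixel to the high-contrast branch.
    bit_depth
        8 or 16; fixes the half-scale constant of the low-contrast rule.
    """
    image = _check_integer(image)
    if radius < 1:
        raise ParameterError(f"radius must be >= 1, got {radius}")
    if radius > image.shape[0] and radius > image.shape[1]:
        raise ParameterError(
            f"radius {radius} exceeds both image dimensions {image.shape}"
        )
    if contrast < 0:
        raise ParameterError(f"contrast must be >= 0, got {contrast}")

    footprint = disk(radius)
    # mode="nearest" clamps out-of-bounds coordinates onto the border pixel in
    # the same rows/cols; the clamped pixel is always itself inside the disk
    # and in bounds, so min/max equal those of the border-clipped neighborhood.
    lo = ndi.minimum_filter(image, footprint=footprint, mode="nearest")
    hi = ndi.maximum_filter(image, footprint=footprint, mode="nearest")
    mid = (lo.astype(np.float64) + hi.astype(np.float64)) / 2.0
    local_contrast = hi.astype(np.float64) - lo.astype(np.float64)

    half_scale = float(2 ** (bit_depth - 1))
    high = local_contrast >= contrast
    fg = np.where(high, image > mid, mid >= half_scale)
    return BinaryMask(
        raster=fg,
        source_channel=source_channel,
        method="bernsen",
        params={"radius": int(radius), "contrast": float(contrast), "bit_depth": bit_depth},
    )


def global_threshold(
    image: np.ndarray,
    t: float,
    source_channel: str = "marker",
) -> BinaryMask:
    """Fixed global threshold: foreground iff intensity strictly exceeds ``t``."""
    image = _check_integer(image)
    top = np.iinfo(image.dtype).max
    if not 0 <= t <= top:
        raise ParameterError(f"threshold {t} outside representable range [0, {top}]")
    return BinaryMask(
        raster=image > t,
        source_channel=source_channel,
        method="global",
        params={"t": float(t)},
    )
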