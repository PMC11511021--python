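"""Color-space conversions on 8-bit sRGB canopy imagery.

Every metric in the toolkit is defined on one of three representations of the
same 8-bit sRGB raster:

* integer HSV with hue in half-degree units (0-179) and saturation/value on
  0-255 -- the convention of the segmentation thresholds;
* CIELAB (D65 white point, 2 degree observer) for the b*/a* opponent ratio;
* chromatic (sum-normalised) rgb for the ExG/CIVE/VEG family.

Conversion math is done in floating point; only the stored ``HsvImage`` is
quantised (round-half-up), so index code never double-rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageOps
from skimage import color as _skcolor

__all__ = [
    "RgbImage",
    "HsvImage",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "rgb_to_lab",
    "rgb_to_chromatic",
    "load_image",
    "save_image",
]


@dataclass
class RgbImage:
    """An 8-bit sRGB raster with provenance tags.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3), uint8
        Channel values 0-255.
    provenance : dict
        Keys ``format`` ("JPEG"/"TIFF"/"synthetic"), ``color_corrected`` and
        ``undistorted`` (bools).
    """

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)
    color_space_tag: str = "sRGB"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"expected H x W x 3 raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        self.provenance.setdefault("format", "synthetic")
        self.provenance.setdefault("color_corrected", False)
        self.provenance.setdefault("undistorted", False)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class HsvImage:
    """HSV raster: hue 0-179 (half-degree units), sat/val 0-255.

    ``quantized`` records whether the arrays are rounded integers (the storage
    convention matching the classification thresholds) or floats.
    """

    hue: np.ndarray
    sat: np.ndarray
    val: np.ndarray
    quantized: bool = True

    @property
    def shape(self) -> tuple:
        return self.hue.shape


def _pixels(img) -> np.ndarray:
    if isinstance(img, RgbImage):
        return img.pixels
    return np.asarray(img)


def rgb_to_hsv(img, quantize: bool = True) -> HsvImage:
    """Hexcone RGB->HSV; hue in half-degree units, sat/val on 0-255.

    Achromatic pixels get hue 0 and saturation 0; consumers must not branch
    on hue when sat == 0.  With ``quantize=True`` hue is round-half-up to the
    nearest integer half-degree and wraps at 180.
    """
    px = _pixels(img).astype(np.float64)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    mx = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    c = mx - mn

    h_deg = np.zeros_like(mx)
    nz = c > 0
    # sector arithmetic on the hexcone
    rmax = nz & (mx == r)
    gmax = nz & (mx == g) & ~rmax
    bmax = nz & (mx == b) & ~rmax & ~gmax
    h_deg[rmax] = (60.0 * ((g[rmax] - b[rmax]) / c[rmax])) % 360.0
    h_deg[gmax] = 60.0 * ((b[gmax] - r[gmax]) / c[gmax]) + 120.0
    h_deg[bmax] = 60.0 * ((r[bmax] - g[bmax]) / c[bmax]) + 240.0

    hue = h_deg / 2.0
    sat = np.where(mx > 0, 255.0 * c / np.where(mx > 0, mx, 1.0), 0.0)
    val = mx
    if quantize:
        hue = np.floor(hue + 0.5).astype(np.int16) % 180
        sat = np.floor(sat + 0.5).astype(np.int16)
        val = val.astype(np.int16)
    return HsvImage(hue=hue, sat=sat, val=val, quantized=quantize)


def hsv_to_rgb(hue, sat, val) -> np.ndarray:
    """Inverse hexcone map; hue 0-179 (half-degrees), sat/val 0-255 -> uint8 RGB."""
    h_deg = np.asarray(hue, dtype=np.float64) * 2.0
    s = np.asarray(sat, dtype=np.float64) / 255.0
    v = np.asarray(val, dtype=np.float64)
    c = v * s
    hp = (h_deg % 360.0) / 60.0
    x = c * (1.0 - np.abs(hp % 2.0 - 1.0))
    z = np.zeros_like(c)
    sector = np.floor(hp).astype(int) % 6
    r = np.select([sector == 0, sector == 1, sector == 2, sector == 3, sector == 4], [c, x, z, z, x], c)
    g = np.select([sector == 0, sector == 1, sector == 2, sector == 3, sector == 4], [x, c, c, x, z], z)
    b = np.select([sector == 0, sector == 1, sector == 2, sector == 3, sector == 4], [z, z, x, c, c], x)
    m = v - c
    rgb = np.stack([r + m, g + m, b + m], axis=-1)
    return np.clip(np.floor(rgb + 0.5), 0, 255).astype(np.uint8)


def rgb_to_lab(img) -> np.ndarray:
    """CIE 1976 L*a*b* (sRGB companding, D65, 2 degree observer).

    Returns a float array of shape (H, W, 3): L* in [0, 100], signed a*/b*.
    """
    px = _pixels(img).astype(np.float64) / 255.0
    return _skcolor.rgb2lab(px)


def rgb_to_chromatic(img):
    """Sum-normalised rgb: r = R/(R+G+B) etc.

    Returns ``(chromatic, valid)`` where ``valid`` is False for pure-black
    pixels (R=G=B=0), which are undefined and excluded from index means.
    """
    px = _pixels(img).astype(np.float64)
    total = px.sum(axis=-1)
    valid = total > 0
    safe = np.where(valid, total, 1.0)
    chrom = px / safe[..., None]
    chrom[~valid] = 0.0
    return chrom, valid


def load_image(path) -> RgbImage:
    """Read a JPEG or TIFF as an 8-bit sRGB :class:`RgbImage`.

    EXIF orientation is honoured; 16-bit TIFF input is reduced to 8 bits by
    dropping the low byte (all processing is done at 8-bit depth).
    """
    path = Path(path)
    with Image.open(path) as im:
        im = ImageOps.exif_transpose(im)
        if im.mode in ("I;16", "I;16B", "I;16L", "I"):
            arr = np.asarray(im, dtype=np.uint32)
            arr = (arr >> 8).astype(np.uint8)
            px = np.stack([arr] * 3, axis=-1) if arr.ndim == 2 else arr
        else:
            px = np.asarray(im.convert("RGB"), dtype=np.uint8)
    suffix = path.suffix.lower()
    fmt = {".tif": "TIFF", ".tiff": "TIFF", ".jpg": "JPEG", ".jpeg": "JPEG"}.get(
        suffix, suffix.lstrip(".").upper() or "UNKNOWN")
    return RgbImage(pixels=px, provenance={"format": fmt})


def save_image(img, path) -> None:
    px = _pixels(img)
    Image.fromarray(px).save(Path(path))
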