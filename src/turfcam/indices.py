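"""Per-image canopy color metrics over the living-cover mask.

All indices are averaged over the %C (living plant material) mask only:

* DGCI  -- dark green color index, ((H-60)/60 + (1-S) + (1-V))/3 with hue in
  degrees and S, V on 0-1; higher means darker green.
* HSVi  -- illumination-modulated hue, (H - S/V)/40 - 0.3 with H on the
  0-179 half-degree scale and S, V on 0-255 (S/V a pure ratio).
* BA    -- CIELAB b*/a* ratio of masked means; negative for green canopies,
  rising toward zero with yellowing.
* ExG, CIVE, VEG and their fixed-weight combination COMB2, all on chromatic
  (sum-normalised) rgb coordinates.

An empty mask yields NaN ("undefined"), never zero: zero is a legal value
for every index here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .colorspace import HsvImage, rgb_to_chromatic, rgb_to_hsv, rgb_to_lab
from .segmentation import CoverMask, RoiSpec, segment_image

__all__ = [
    "MetricRecord",
    "METRIC_COLUMNS",
    "dgci",
    "hsvi",
    "ba_ratio",
    "chromatic_indices",
    "comb2",
    "summarize_image",
]

#: VEG denominator floor: keeps r^a * b^(1-a) finite for pure-green pixels
#: without materially shifting canopy means (one count in 3*255^2).
VEG_EPS = 1.0 / (3.0 * 255.0**2)

#: COMB2 = 0.36*ExG + 0.47*CIVE + 0.17*VEG
COMB2_WEIGHTS = (0.36, 0.47, 0.17)

METRIC_COLUMNS = ["pct_c", "pct_y", "pct_g", "dgci", "hsvi", "ba", "exg", "cive", "veg", "comb2"]


@dataclass
class MetricRecord:
    """One image's cover fractions and color indices.

    Undefined metrics (empty living-cover mask, achromatic canopy) are NaN.
    ``hsv_convention`` records the channel scaling used inside DGCI/HSVi.
    """

    sample_id: str = ""
    replicate_id: str = ""
    variant: dict = field(default_factory=dict)
    pct_c: float = math.nan
    pct_y: float = math.nan
    pct_g: float = math.nan
    dgci: float = math.nan
    hsvi: float = math.nan
    ba: float = math.nan
    exg: float = math.nan
    cive: float = math.nan
    veg: float = math.nan
    comb2: float = math.nan
    n_mask_pixels: int = 0
    hsv_convention: str = "H:0-179(quantized) S,V:0-255"

    def as_dict(self) -> dict:
        d = {
            "sample_id": self.sample_id,
            "replicate_id": self.replicate_id,
            "variant": variant_label(self.variant),
        }
        for k in METRIC_COLUMNS:
            d[k] = getattr(self, k)
        d["n_mask_pixels"] = self.n_mask_pixels
        return d


def variant_label(variant: dict) -> str:
    """Study-style label, e.g. 'JPG LC CC' / 'TIF'."""
    if not variant:
        return ""
    if isinstance(variant, str):
        return variant
    parts = [variant.get("format", "JPG")]
    if variant.get("lens_corrected"):
        parts.append("LC")
    if variant.get("color_corrected"):
        parts.append("CC")
    return " ".join(parts)


def _masked(arrs, mask):
    m = mask.mask if isinstance(mask, CoverMask) else np.asarray(mask)
    return [np.asarray(a)[m] for a in arrs], m


def dgci(hsv: HsvImage, mask) -> float:
    """Mean dark green color index over the mask (NaN if mask is empty)."""
    (h, s, v), _ = _masked((hsv.hue, hsv.sat, hsv.val), mask)
    if h.size == 0:
        return math.nan
    h_deg = h.astype(np.float64) * 2.0
    s01 = s.astype(np.float64) / 255.0
    v01 = v.astype(np.float64) / 255.0
    return float(np.mean(((h_deg - 60.0) / 60.0 + (1.0 - s01) + (1.0 - v01)) / 3.0))


def hsvi(hsv: HsvImage, mask) -> float:
    """Mean (H - S/V)/40 - 0.3 over the mask; V=0 pixels are excluded."""
    (h, s, v), _ = _masked((hsv.hue, hsv.sat, hsv.val), mask)
    ok = v > 0
    if not np.any(ok):
        return math.nan
    h = h[ok].astype(np.float64)
    ratio = s[ok].astype(np.float64) / v[ok].astype(np.float64)
    return float(np.mean((h - ratio) / 40.0 - 0.3))


def ba_ratio(lab: np.ndarray, mask) -> float:
    """Ratio of masked-mean b* to masked-mean a*.

    Uses the ratio of means rather than the mean of per-pixel ratios: a*
    crosses zero on mixed canopies, which makes per-pixel ratios unstable.
    Near-achromatic canopies (|mean a*| < 0.05, e.g. gray frames, whose a*
    is not exactly zero under the standard sRGB->Lab matrices) are
    undefined.
    """
    (a, b), _ = _masked((lab[..., 1], lab[..., 2]), mask)
    if a.size == 0:
        return math.nan
    ma = float(np.mean(a))
    if abs(ma) < 0.05:
        return math.nan
    return float(np.mean(b)) / ma


def chromatic_indices(rgb, mask) -> tuple:
    """Masked means of ExG, CIVE and VEG on chromatic coordinates.

    Pure-black pixels (undefined chromatic coordinates) are excluded; the VEG
    denominator channels are floored at :data:`VEG_EPS`.
    """
    chrom, valid = rgb_to_chromatic(rgb)
    m = mask.mask if isinstance(mask, CoverMask) else np.asarray(mask)
    m = m & valid
    if not np.any(m):
        return math.nan, math.nan, math.nan
    r, g, b = chrom[..., 0][m], chrom[..., 1][m], chrom[..., 2][m]
    exg = 2.0 * g - r - b
    cive = 0.441 * r - 0.911 * g + 0.385 * b + 18.78745
    rf = np.maximum(r, VEG_EPS)
    bf = np.maximum(b, VEG_EPS)
    veg = g / (rf**0.667 * bf ** (1.0 - 0.667))
    return float(exg.mean()), float(cive.mean()), float(veg.mean())


def comb2(exg: float, cive: float, veg: float) -> float:
    """Fixed-weight combination of the three chromatic indices."""
    if any(map(math.isnan, (exg, cive, veg))):
        return math.nan
    w = COMB2_WEIGHTS
    return w[0] * exg + w[1] * cive + w[2] * veg


def summarize_image(img, rules=None, roi: RoiSpec | None = None, sample_id: str = "",
                    replicate_id: str = "", variant: dict | None = None) -> MetricRecord:
    """Compute the full metric vector for one image.

    Cover fractions come from the rule set over the ROI; every color index is
    computed strictly over the living-cover (%C) mask.  With an empty %C mask
    the fractions are still reported and the indices are NaN.
    """
    fractions, c_mask = segment_image(img, rules=rules, roi=roi)
    hsv = rgb_to_hsv(img)
    rec = MetricRecord(
        sample_id=sample_id,
        replicate_id=replicate_id,
        variant=variant or {},
        pct_c=fractions.get("%C", math.nan),
        pct_y=fractions.get("%Y", math.nan),
        pct_g=fractions.get("%G", math.nan),
        n_mask_pixels=c_mask.count,
    )
    if c_mask.count > 0:
        rec.dgci = dgci(hsv, c_mask)
        rec.hsvi = hsvi(hsv, c_mask)
        rec.ba = ba_ratio(rgb_to_lab(img), c_mask)
        rec.exg, rec.cive, rec.veg = chromatic_indices(img, c_mask)
        rec.comb2 = comb2(rec.exg, rec.cive, rec.veg)
    return rec
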