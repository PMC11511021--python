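"""Cover-class segmentation and ROI-referenced fractional areas.

Pixels are classified by inclusive HSV interval rules into three canopy cover
classes: total living plant material (%C), yellow senescent material (%Y) and
healthy green material (%G).  Fractional areas are referenced to the circular
lysimeter-top region of interest, not the frame, so leaves that extend past
the vessel perimeter can push a fraction above 100%.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass

import numpy as np

from .colorspace import HsvImage, RgbImage, rgb_to_hsv

__all__ = [
    "ClassificationRule",
    "RoiSpec",
    "CoverMask",
    "DEFAULT_RULES",
    "classify",
    "fractional_area",
    "segment_image",
    "load_rules",
    "save_mask_png",
]


@dataclass(frozen=True)
class ClassificationRule:
    """Inclusive hue/saturation/value ranges defining one cover class.

    Hue is on the 0-179 half-degree scale, saturation and value on 0-255.
    A pixel belongs to the class iff all three interval tests pass (both
    endpoints included).
    """

    name: str
    hue_min: int
    hue_max: int
    sat_min: int = 60
    sat_max: int = 255
    val_min: int = 1
    val_max: int = 255

    def __post_init__(self):
        for lo, hi, top in (
            (self.hue_min, self.hue_max, 179),
            (self.sat_min, self.sat_max, 255),
            (self.val_min, self.val_max, 255),
        ):
            if not (0 <= lo <= hi <= top):
                raise ValueError(f"invalid rule bounds for {self.name!r}: {lo}..{hi}")

    def contains(self, hue, sat, val):
        """Vectorised inclusive interval test."""
        return (
            (hue >= self.hue_min)
            & (hue <= self.hue_max)
            & (sat >= self.sat_min)
            & (sat <= self.sat_max)
            & (val >= self.val_min)
            & (val <= self.val_max)
        )


#: Default thresholds: living cover, yellow senescent, healthy green.
#: Saturation >= 60 excludes the white background; value 0 (pure black) is
#: excluded.  Note %G is a hue sub-range of %C and %Y is hue-disjoint from it.
DEFAULT_RULES = {
    "%C": ClassificationRule("%C", 27, 90),
    "%Y": ClassificationRule("%Y", 16, 26),
    "%G": ClassificationRule("%G", 30, 60),
}


@dataclass(frozen=True)
class RoiSpec:
    """Circular region of interest (the lysimeter top) in pixel coordinates.

    ``radius`` in pixels defines the reference area pi*r^2 used as the
    denominator of every fractional cover value.
    """

    center: tuple  # (row, col)
    radius: float  # pixels

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")

    @classmethod
    def from_physical(cls, image_shape, diameter_cm: float = 16.0, px_per_mm: float = 11.0, center=None):
        """ROI from physical vessel diameter and imaging resolution.

        Defaults match a 16 cm diameter vessel imaged at ~11 px/mm.  The disk
        is centred on the frame unless ``center`` is given.
        """
        radius = diameter_cm * 10.0 * px_per_mm / 2.0
        if center is None:
            center = ((image_shape[0] - 1) / 2.0, (image_shape[1] - 1) / 2.0)
        return cls(center=center, radius=radius)

    @property
    def reference_area(self) -> float:
        return math.pi * self.radius**2

    def disk_mask(self, shape) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius**2


@dataclass
class CoverMask:
    """Boolean raster marking the pixels of one cover class."""

    mask: np.ndarray
    rule_name: str

    @property
    def count(self) -> int:
        return int(self.mask.sum())


def classify(hsv: HsvImage, rule: ClassificationRule) -> CoverMask:
    """Classify each pixel by the rule's three inclusive interval tests."""
    return CoverMask(mask=rule.contains(hsv.hue, hsv.sat, hsv.val), rule_name=rule.name)


def fractional_area(mask: CoverMask, roi: RoiSpec) -> float:
    """Class pixel count over the ROI disk area, as a percentage.

    The numerator counts the whole frame while the denominator is the ROI
    reference area, so values can exceed 100 when leaves overhang the vessel
    perimeter.
    """
    return 100.0 * mask.count / roi.reference_area


def segment_image(img, rules=None, roi: RoiSpec | None = None):
    """Segment an image into cover fractions.

    Returns ``(fractions, c_mask)`` where ``fractions`` maps rule name to
    percent of the ROI reference area and ``c_mask`` is the living-cover
    (%C) mask that supports all downstream color-index computations.
    """
    if rules is None:
        rules = DEFAULT_RULES
    if isinstance(rules, (list, tuple)):
        rules = {r.name: r for r in rules}
    if "%C" not in rules:
        raise ValueError("rule set must include the living-cover class '%C'")
    px = img.pixels if isinstance(img, RgbImage) else np.asarray(img)
    if roi is None:
        # largest centred disk that fits the frame
        roi = RoiSpec(
            center=((px.shape[0] - 1) / 2.0, (px.shape[1] - 1) / 2.0),
            radius=min(px.shape[0], px.shape[1]) / 2.0,
        )
    hsv = rgb_to_hsv(px)
    fractions = {}
    c_mask = None
    for name, rule in rules.items():
        m = classify(hsv, rule)
        fractions[name] = fractional_area(m, roi)
        if name == "%C":
            c_mask = m
    return fractions, c_mask


def load_rules(path) -> dict:
    """Load classification rules from a TOML file.

    Expected layout::

        ["%C"]
        hue = [27, 90]
        sat = [60, 255]
        val = [1, 255]
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    rules = {}
    for name, spec in raw.items():
        hue = spec.get("hue")
        sat = spec.get("sat", [60, 255])
        val = spec.get("val", [1, 255])
        rules[name] = ClassificationRule(name, hue[0], hue[1], sat[0], sat[1], val[0], val[1])
    return rules


def save_mask_png(mask: CoverMask, path) -> None:
    """Write a mask as a 1-bit PNG for visual audit."""
    from PIL import Image

    Image.fromarray(mask.mask).convert("1").save(path)
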