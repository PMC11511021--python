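"""Image corrections: color-checker color mapping and radial lens distortion.

Two correction families are fitted from reference targets photographed in the
same lightbox as the canopy samples:

* **Color correction** from a 24-patch checker: either a least-squares affine
  3x3 + offset map in sRGB, or per-channel monotone lookup tables.
* **Radial lens distortion** from a dot-grid target: a center plus a radial
  polynomial mapping undistorted radius to distorted radius (the backward
  model, which is exactly what an inverse remap needs).

When both corrections are applied, color correction comes first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial import cKDTree

from .colorspace import RgbImage

__all__ = [
    "PatchSet",
    "ColorCorrectionModel",
    "DistortionModel",
    "fit_color_correction",
    "apply_color_correction",
    "detect_grid_points",
    "fit_distortion",
    "undistort",
    "distort_image",
]


@dataclass
class PatchSet:
    """24 paired sRGB triples: measured (chart photo) vs reference (published).

    Patch order is fixed row-major chart order.
    """

    measured: np.ndarray  # (24, 3) floats 0-255
    reference: np.ndarray  # (24, 3) floats 0-255

    def __post_init__(self):
        self.measured = np.asarray(self.measured, dtype=np.float64)
        self.reference = np.asarray(self.reference, dtype=np.float64)
        if self.measured.shape != (24, 3) or self.reference.shape != (24, 3):
            raise ValueError("a patch set is exactly 24 paired sRGB triples")


@dataclass
class ColorCorrectionModel:
    """Color mapping: affine ``ref ~ matrix @ measured + offset`` or channel LUTs."""

    kind: str = "affine"  # "affine" | "lut"
    matrix: np.ndarray | None = None  # (3, 3)
    offset: np.ndarray | None = None  # (3,)
    luts: np.ndarray | None = None  # (3, 256)
    rmse: float = 0.0

    @classmethod
    def identity(cls) -> "ColorCorrectionModel":
        return cls(kind="affine", matrix=np.eye(3), offset=np.zeros(3), rmse=0.0)

    def apply_to_colors(self, colors: np.ndarray) -> np.ndarray:
        """Map float sRGB triples (..., 3); no clipping or rounding."""
        c = np.asarray(colors, dtype=np.float64)
        if self.kind == "affine":
            return c @ self.matrix.T + self.offset
        idx = np.clip(c, 0, 255)
        out = np.empty_like(c)
        base = np.arange(256, dtype=np.float64)
        for ch in range(3):
            out[..., ch] = np.interp(idx[..., ch], base, self.luts[ch])
        return out

    def to_json(self, path=None) -> str:
        payload = {"kind": self.kind, "rmse": self.rmse}
        if self.kind == "affine":
            payload["matrix"] = self.matrix.tolist()
            payload["offset"] = self.offset.tolist()
        else:
            payload["luts"] = self.luts.tolist()
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ColorCorrectionModel":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and Path(source).exists() else source
        d = json.loads(text)
        m = cls(kind=d["kind"], rmse=d.get("rmse", 0.0))
        if m.kind == "affine":
            m.matrix = np.asarray(d["matrix"], dtype=np.float64)
            m.offset = np.asarray(d["offset"], dtype=np.float64)
        else:
            m.luts = np.asarray(d["luts"], dtype=np.float64)
        return m


def fit_color_correction(patches: PatchSet, kind: str = "affine") -> ColorCorrectionModel:
    """Fit a color correction from measured->reference patch pairs.

    affine: least-squares 3x3 matrix + offset minimising the summed squared
    sRGB residual over the 24 patches.  lut: per-channel monotone
    interpolation through the (measured, reference) pairs.  The model's
    ``rmse`` is the per-channel root-mean-square residual over patches.
    """
    X = np.hstack([patches.measured, np.ones((24, 1))])
    if kind == "affine":
        if np.linalg.matrix_rank(X) < 4:
            raise ValueError("degenerate patch set: affine fit is rank-deficient")
        coef, *_ = np.linalg.lstsq(X, patches.reference, rcond=None)
        matrix = coef[:3].T
        offset = coef[3]
        pred = patches.measured @ matrix.T + offset
        rmse = float(np.sqrt(np.mean((pred - patches.reference) ** 2)))
        return ColorCorrectionModel(kind="affine", matrix=matrix, offset=offset, rmse=rmse)
    if kind == "lut":
        base = np.arange(256, dtype=np.float64)
        luts = np.empty((3, 256))
        for ch in range(3):
            order = np.argsort(patches.measured[:, ch], kind="stable")
            xs = patches.measured[order, ch]
            ys = patches.reference[order, ch]
            # average duplicate abscissae, then enforce monotone targets
            ux, inv = np.unique(xs, return_inverse=True)
            uy = np.bincount(inv, weights=ys) / np.bincount(inv)
            uy = np.maximum.accumulate(uy)
            luts[ch] = np.clip(np.interp(base, ux, uy), 0, 255)
        model = ColorCorrectionModel(kind="lut", luts=luts)
        pred = model.apply_to_colors(patches.measured)
        model.rmse = float(np.sqrt(np.mean((pred - patches.reference) ** 2)))
        return model
    raise ValueError(f"unknown color-correction kind {kind!r}")


def apply_color_correction(img, model: ColorCorrectionModel) -> RgbImage:
    """Apply a color mapping per pixel; results clipped to [0, 255] and rounded."""
    px = img.pixels if isinstance(img, RgbImage) else np.asarray(img)
    out = model.apply_to_colors(px.astype(np.float64))
    out = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    prov = dict(img.provenance) if isinstance(img, RgbImage) else {}
    prov["color_corrected"] = True
    return RgbImage(pixels=out, provenance=prov)


# ---------------------------------------------------------------------------
# radial lens distortion
# ---------------------------------------------------------------------------


@dataclass
class DistortionModel:
    """Radial distortion: r_distorted = r_u * (k0 + k1*r_u + k2*r_u^2 + ...).

    ``center`` is (x, y) in pixel coordinates (col, row).  The polynomial maps
    undistorted radius to distorted radius (backward model); the identity is
    k0 = 1 with all higher coefficients zero.
    """

    center: tuple
    radial_coeffs: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    residual_px: float = 0.0

    def __post_init__(self):
        self.radial_coeffs = np.asarray(self.radial_coeffs, dtype=np.float64)

    @property
    def is_identity(self) -> bool:
        k = self.radial_coeffs
        return k[0] == 1.0 and (k.size == 1 or not np.any(k[1:]))

    def _factor(self, r_u: np.ndarray) -> np.ndarray:
        # k0 + k1*r + k2*r^2 + ... evaluated at undistorted radius
        return np.polynomial.polynomial.polyval(r_u, self.radial_coeffs)

    def distorted_radius(self, r_u):
        r_u = np.asarray(r_u, dtype=np.float64)
        return r_u * self._factor(r_u)

    def undistorted_radius(self, r_d, n_iter: int = 25):
        """Invert the radius map by Newton iteration (vectorised)."""
        r_d = np.asarray(r_d, dtype=np.float64)
        k = self.radial_coeffs
        dk = k[1:] * np.arange(1, k.size)  # derivative of the factor
        r = r_d.copy()
        for _ in range(n_iter):
            f = np.polynomial.polynomial.polyval(r, k)
            df = np.polynomial.polynomial.polyval(r, dk) if dk.size else 0.0
            g = r * f - r_d
            gp = f + r * df
            r = r - g / np.where(np.abs(gp) > 1e-12, gp, 1e-12)
            r = np.maximum(r, 0.0)
        return r

    def distort_points(self, pts: np.ndarray) -> np.ndarray:
        """Forward map: undistorted (x, y) points -> distorted positions."""
        p = np.asarray(pts, dtype=np.float64) - self.center
        r_u = np.hypot(p[..., 0], p[..., 1])
        scale = np.where(r_u > 0, self.distorted_radius(r_u) / np.where(r_u > 0, r_u, 1.0), 1.0)
        return p * scale[..., None] + self.center

    def undistort_points(self, pts: np.ndarray) -> np.ndarray:
        p = np.asarray(pts, dtype=np.float64) - self.center
        r_d = np.hypot(p[..., 0], p[..., 1])
        r_u = self.undistorted_radius(r_d)
        scale = np.where(r_d > 0, r_u / np.where(r_d > 0, r_d, 1.0), 1.0)
        return p * scale[..., None] + self.center

    def is_monotone(self, r_max: float, n: int = 512) -> bool:
        r = np.linspace(0, r_max, n)
        return bool(np.all(np.diff(self.distorted_radius(r)) > 0))

    def to_json(self, path=None) -> str:
        payload = {
            "center": list(self.center),
            "radial_coeffs": self.radial_coeffs.tolist(),
            "residual_px": self.residual_px,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DistortionModel":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and Path(source).exists() else source
        d = json.loads(text)
        return cls(center=tuple(d["center"]), radial_coeffs=np.asarray(d["radial_coeffs"]),
                   residual_px=d.get("residual_px", 0.0))


def detect_grid_points(grid_img, spacing_hint: float | None = None, dark_threshold: int = 128):
    """Locate dot centers on a grid target and group them into lines.

    Returns ``(points, rows, cols)``: intensity-weighted subpixel centers as
    (x, y) pairs, plus index lists grouping them into horizontal rows and
    vertical columns.  Raises ValueError when fewer than 3 lines are found on
    either axis (insufficient target).
    """
    px = grid_img.pixels if isinstance(grid_img, RgbImage) else np.asarray(grid_img)
    gray = px.mean(axis=-1) if px.ndim == 3 else px.astype(np.float64)
    darkness = np.clip(255.0 - gray, 0, None)
    blobs = gray < dark_threshold
    labels, n = ndimage.label(blobs)
    if n < 9:
        raise ValueError("insufficient target: fewer than 9 grid dots detected")
    # intensity-weighted centroids -> subpixel (row, col)
    centers_rc = ndimage.center_of_mass(darkness, labels, index=np.arange(1, n + 1))
    pts = np.array([(c, r) for r, c in centers_rc])  # (x, y)

    if spacing_hint is None:
        tree = cKDTree(pts)
        dist, _ = tree.query(pts, k=2)
        spacing_hint = float(np.median(dist[:, 1]))

    def group(coord):
        order = np.argsort(coord)
        groups, current = [], [order[0]]
        for idx in order[1:]:
            ref = np.mean(coord[current])
            if coord[idx] - ref > 0.5 * spacing_hint:
                groups.append(current)
                current = [idx]
            else:
                current.append(idx)
        groups.append(current)
        return [np.array(g) for g in groups]

    rows = group(pts[:, 1])
    cols = group(pts[:, 0])
    if len(rows) < 3 or len(cols) < 3:
        raise ValueError("insufficient target: fewer than 3 lines per axis")
    return pts, rows, cols


def _line_residuals(groups_pts):
    """Perpendicular deviations of each group's points from its best-fit line."""
    res = []
    for g in groups_pts:
        c = g - g.mean(axis=0)
        # smallest principal axis = line normal
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        res.append(c @ vt[-1])
    return np.concatenate(res)


def fit_distortion(points: np.ndarray, rows, cols, degree: int = 3, center0=None,
                   image_shape=None) -> DistortionModel:
    """Fit center + radial polynomial so corrected grid lines are straight.

    ``points`` are detected (x, y) dot centers; ``rows``/``cols`` are index
    groups from :func:`detect_grid_points`.  k0 is fixed at 1 (straightness
    is invariant to a global scale); the free parameters are the center and
    k1..k_degree.  The fit is rejected if the resulting radius map is not
    monotone over the point cloud.  ``residual_px`` reports the maximum
    perpendicular deviation of corrected points from their lines.
    """
    pts = np.asarray(points, dtype=np.float64)
    if center0 is None:
        if image_shape is not None:
            center0 = ((image_shape[1] - 1) / 2.0, (image_shape[0] - 1) / 2.0)
        else:
            center0 = tuple(pts.mean(axis=0))
    r_scale = float(np.max(np.hypot(pts[:, 0] - center0[0], pts[:, 1] - center0[1])))
    groups = [pts[g] for g in rows] + [pts[g] for g in cols]

    def model_from(params):
        xc, yc = params[0], params[1]
        a = params[2:]
        coeffs = np.concatenate([[1.0], a / r_scale ** np.arange(1, degree + 1)])
        return DistortionModel(center=(xc, yc), radial_coeffs=coeffs)

    def residuals(params):
        m = model_from(params)
        corrected = [m.undistort_points(g) for g in groups]
        return _line_residuals(corrected)

    x0 = np.concatenate([[center0[0], center0[1]], np.zeros(degree)])
    if degree == 0:
        model = DistortionModel(center=center0, radial_coeffs=np.array([1.0]))
        model.residual_px = float(np.max(np.abs(_line_residuals(groups))))
        return model
    sol = optimize.least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12)
    model = model_from(sol.x)
    r_max = float(np.max(np.hypot(pts[:, 0] - model.center[0], pts[:, 1] - model.center[1])))
    if not model.is_monotone(r_max * 1.05):
        raise ValueError("fit rejected: radius map is not monotone over the target")
    model.residual_px = float(np.max(np.abs(residuals(sol.x))))
    return model


def _remap(px: np.ndarray, map_xy, cval: float) -> np.ndarray:
    """Bilinear inverse remap of an RGB uint8 raster."""
    h, w = px.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    src_x, src_y = map_xy(xx.astype(np.float64), yy.astype(np.float64))
    coords = np.stack([src_y.ravel(), src_x.ravel()])
    out = np.empty_like(px)
    for ch in range(3):
        vals = ndimage.map_coordinates(px[..., ch].astype(np.float64), coords, order=1,
                                       mode="constant", cval=cval)
        out[..., ch] = np.clip(np.floor(vals.reshape(h, w) + 0.5), 0, 255).astype(np.uint8)
    return out


def undistort(img, model: DistortionModel) -> RgbImage:
    """Correct radial distortion by inverse remap with bilinear interpolation.

    Out-of-source pixels are filled white (the lightbox background).  The
    identity model returns the image bit-exactly.
    """
    px = img.pixels if isinstance(img, RgbImage) else np.asarray(img)
    prov = dict(img.provenance) if isinstance(img, RgbImage) else {}
    prov["undistorted"] = True
    if model.is_identity:
        return RgbImage(pixels=px.copy(), provenance=prov)

    def map_xy(xx, yy):
        pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
        src = model.distort_points(pts)  # output (undistorted) -> source (distorted)
        return src[:, 0].reshape(xx.shape), src[:, 1].reshape(yy.shape)

    return RgbImage(pixels=_remap(px, map_xy, cval=255.0), provenance=prov)


def distort_image(img, model: DistortionModel, cval: float = 255.0) -> RgbImage:
    """Forward-distort a clean image (used to synthesise camera distortion)."""
    px = img.pixels if isinstance(img, RgbImage) else np.asarray(img)
    prov = dict(img.provenance) if isinstance(img, RgbImage) else {}
    if model.is_identity:
        return RgbImage(pixels=px.copy(), provenance=prov)

    def map_xy(xx, yy):
        pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
        src = model.undistort_points(pts)  # output (distorted) -> source (clean)
        return src[:, 0].reshape(xx.shape), src[:, 1].reshape(yy.shape)

    return RgbImage(pixels=_remap(px, map_xy, cval=cval), provenance=prov)
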