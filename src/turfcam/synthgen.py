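"""Synthetic inputs: canopy scenes, calibration targets, and study tables.

Everything the toolkit consumes can be generated here with known ground
truth:

* canopy scenes — a circular vessel-top region on a white background covered
  by hard-edged green/yellow leaf strokes whose HSV distributions are
  controllable, with optional color cast, radial distortion, and LED
  illumination drift;
* color-checker and dot-grid calibration targets with injected casts and
  distortions;
* full factorial study tables (mowing height x irrigation x date) with
  treatment effects on the yellow/green fractions and emulated reference
  covariates (visual quality ratings, NDVI/NDRE and band reflectances,
  clipping production, water use).

Every generator is a pure function of its parameters and seed.  Leaf strokes
are rendered without anti-aliasing so every pixel has an unambiguous class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from .colorspace import RgbImage, hsv_to_rgb
from .corrections import ColorCorrectionModel, DistortionModel, PatchSet, distort_image
from .segmentation import DEFAULT_RULES, RoiSpec

__all__ = [
    "IlluminationModel",
    "illumination",
    "CanopyScene",
    "make_canopy_scene",
    "make_checker_target",
    "synthetic_reference_patches",
    "make_grid_target",
    "GridTarget",
    "SyntheticStudyConfig",
    "simulate_study",
]


# ---------------------------------------------------------------------------
# LED illumination drift
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IlluminationModel:
    """Quadratic LED warm-up decay with a steady state.

    The default coefficients describe a low-cost LED strip whose output fell
    from ~16.5 to a steady 8 W m^-2 over the first 360 s after switch-on:
    radiation(t) = a t^2 + b t + c for t < steady_after, else steady_state.
    """

    a: float = 0.00005
    b: float = -0.0309
    c: float = 16.494
    steady_state: float = 8.0
    steady_after: float = 360.0

    def polynomial(self, t):
        t = np.asarray(t, dtype=np.float64)
        return self.a * t**2 + self.b * t + self.c


def illumination(t, model: IlluminationModel | None = None):
    """Irradiance (W m^-2) at time t seconds after the lights switch on."""
    if model is None:
        model = IlluminationModel()
    t_arr = np.asarray(t, dtype=np.float64)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = np.where(t_arr < model.steady_after, model.polynomial(t_arr), model.steady_state)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# canopy scenes
# ---------------------------------------------------------------------------


@dataclass
class CanopyScene:
    """A rendered scene plus exact per-pixel ground truth.

    ``labels``: 0 background, 1 green stroke, 2 yellow stroke.  ``truth``
    holds per-rule pixel counts/fractions evaluated on the generated integer
    HSV raster (so boundary effects of the renderer are impossible), the mean
    HSV of living material, and any injected cast/distortion parameters.
    ``image`` is the degraded frame when a cast/distortion was injected;
    ``clean_image`` is always the undegraded render.
    """

    image: RgbImage
    clean_image: RgbImage
    labels: np.ndarray
    truth: dict
    roi: RoiSpec
    seed: int


DEFAULT_GREEN_HUE = (29, 62)
DEFAULT_YELLOW_HUE = (18, 24)
DEFAULT_SAT = (80, 220)
DEFAULT_VAL = (80, 230)


def _paint_class(rng, rgb, hsv_raster, labels, roi, label_value, hue_range, sat_range,
                 val_range, target_px, light_factor, px_per_mm, patch_centers=None,
                 patch_sd=None):
    """Paint elliptical blade strokes until the class covers target_px pixels.

    Stroke size is physical (blade half-length 4-9 mm, half-width 1-2.5 mm)
    so edge-to-area ratio tracks the imaging resolution.
    """
    h_img, w_img = labels.shape
    painted = int(np.sum(labels == label_value))
    guard = 0
    big_area = math.pi * 9 * 2.5 * px_per_mm**2
    while painted < target_px:
        guard += 1
        if guard > 200000:
            raise RuntimeError("infeasible coverage request: frame capacity exceeded")
        remaining = target_px - painted
        if remaining > max(400.0, 1.05 * big_area):
            a_ax = px_per_mm * rng.uniform(4.0, 9.0)
            b_ax = max(1.2, px_per_mm * rng.uniform(1.0, 2.5))
        elif remaining > 150:
            a_ax = max(2.0, px_per_mm * 1.5)
            b_ax = max(1.2, px_per_mm * 0.8)
        else:
            a_ax, b_ax = 1.6, 1.2
        if patch_centers is not None:
            pc = patch_centers[rng.integers(len(patch_centers))]
            rc = pc[0] + rng.normal(0.0, patch_sd)
            cc = pc[1] + rng.normal(0.0, patch_sd)
        else:
            rc = roi.center[0] + rng.uniform(-1.0, 1.0) * roi.radius
            cc = roi.center[1] + rng.uniform(-1.0, 1.0) * roi.radius
        rot = rng.uniform(0, math.pi)
        rr, cx = _draw_ellipse(rc, cc, a_ax, b_ax, shape=(h_img, w_img), rotation=rot)
        if rr.size == 0:
            continue
        hue = rng.integers(hue_range[0], hue_range[1] + 1)
        sat = rng.integers(sat_range[0], sat_range[1] + 1)
        val = int(np.clip(round(rng.integers(val_range[0], val_range[1] + 1) * light_factor),
                          val_range[0], 255))
        color = hsv_to_rgb(np.array(hue), np.array(sat), np.array(val))
        prev = labels[rr, cx].copy()
        labels[rr, cx] = label_value
        rgb[rr, cx] = color
        hsv_raster[rr, cx] = (hue, sat, val)
        painted += int(np.sum(prev != label_value))
        # overwriting strokes can shrink the other class; caller repaints
    return painted


def make_canopy_scene(shape=(360, 360), diameter_cm: float = 16.0, px_per_mm: float = 1.0,
                      green_cover: float = 0.5, yellow_cover: float = 0.15,
                      green_hue=DEFAULT_GREEN_HUE, yellow_hue=DEFAULT_YELLOW_HUE,
                      sat_range=DEFAULT_SAT, val_range=DEFAULT_VAL,
                      cast: ColorCorrectionModel | None = None,
                      distortion: DistortionModel | None = None,
                      illumination_t: float | None = None,
                      illumination_model: IlluminationModel | None = None,
                      seed: int = 0) -> CanopyScene:
    """Render a synthetic vessel-top canopy scene with exact ground truth.

    ``green_cover``/``yellow_cover`` are target fractions of the ROI disk
    area (may sum past what the frame can hold, in which case an error is
    raised).  Hue/sat/val are sampled uniformly on the given integer ranges,
    chosen by default to sit strictly inside the classification thresholds.
    ``illumination_t`` scales stroke brightness by the LED drift model at
    that time; ``cast``/``distortion`` degrade the output frame while the
    clean render and truth are retained.
    """
    rng = np.random.default_rng(seed)
    roi = RoiSpec.from_physical(shape, diameter_cm=diameter_cm, px_per_mm=px_per_mm)
    if roi.radius > min(shape) / 2.0 + 0.5:
        raise ValueError("ROI does not fit the frame; reduce px_per_mm or diameter")
    if not (0 <= green_cover <= 1.5 and 0 <= yellow_cover <= 1.5):
        raise ValueError("cover targets must lie in [0, 1.5] of the ROI area")
    capacity = shape[0] * shape[1]
    disk = roi.reference_area
    if (green_cover + yellow_cover) * disk > 0.95 * capacity:
        raise ValueError("infeasible coverage request exceeds frame capacity")

    rgb = np.full(shape + (3,), 255, dtype=np.uint8)
    labels = np.zeros(shape, dtype=np.uint8)
    hsv_raster = np.zeros(shape + (3,), dtype=np.int16)

    light_factor = 1.0
    if illumination_t is not None:
        model = illumination_model or IlluminationModel()
        light_factor = float(illumination(illumination_t, model) / model.polynomial(0.0))

    g_target = int(round(green_cover * disk))
    y_target = int(round(yellow_cover * disk))
    # senescent material clusters spatially: yellow strokes concentrate
    # around a few patch centers instead of interleaving blade-by-blade
    n_patches = max(2, int(round(3 + 4 * yellow_cover)))
    angles = rng.uniform(0, 2 * math.pi, n_patches)
    radii = roi.radius * np.sqrt(rng.uniform(0.05, 0.9, n_patches))
    patch_centers = np.stack([roi.center[0] + radii * np.sin(angles),
                              roi.center[1] + radii * np.cos(angles)], axis=1)
    patch_sd = max(10.0, 12.0 * px_per_mm)
    # paint alternately so overwrites settle; two passes suffice in practice
    for _ in range(8):
        if g_target:
            _paint_class(rng, rgb, hsv_raster, labels, roi, 1, green_hue, sat_range,
                         val_range, g_target, light_factor, px_per_mm)
        if y_target:
            _paint_class(rng, rgb, hsv_raster, labels, roi, 2, yellow_hue, sat_range,
                         val_range, y_target, light_factor, px_per_mm,
                         patch_centers=patch_centers, patch_sd=patch_sd)
        ng = int(np.sum(labels == 1))
        ny = int(np.sum(labels == 2))
        if ng >= g_target and ny >= y_target:
            break

    # ground truth evaluated on the generated integer HSV values
    truth_counts = {}
    occupied = labels > 0
    h, s, v = hsv_raster[..., 0], hsv_raster[..., 1], hsv_raster[..., 2]
    for name, rule in DEFAULT_RULES.items():
        truth_counts[name] = int(np.sum(rule.contains(h, s, v) & occupied))
    living = occupied & (labels == 1)
    mean_hsv = tuple(float(hsv_raster[..., i][living].mean()) if living.any() else math.nan
                     for i in range(3))

    clean = RgbImage(pixels=rgb, provenance={"format": "synthetic"})
    degraded = clean
    if cast is not None:
        degraded = RgbImage(
            pixels=np.clip(np.floor(cast.apply_to_colors(degraded.pixels.astype(float)) + 0.5),
                           0, 255).astype(np.uint8),
            provenance=dict(degraded.provenance),
        )
    if distortion is not None:
        degraded = distort_image(degraded, distortion)

    truth = {
        "counts": truth_counts,
        "fractions_pct": {k: 100.0 * c / disk for k, c in truth_counts.items()},
        "label_counts": {"green": int(np.sum(labels == 1)), "yellow": int(np.sum(labels == 2))},
        "mean_hsv_living": mean_hsv,
        "light_factor": light_factor,
        "cast": None if cast is None else "affine",
        "distortion": None if distortion is None else list(map(float, distortion.radial_coeffs)),
    }
    return CanopyScene(image=degraded, clean_image=clean, labels=labels, truth=truth,
                       roi=roi, seed=seed)


# ---------------------------------------------------------------------------
# calibration targets
# ---------------------------------------------------------------------------


def synthetic_reference_patches() -> np.ndarray:
    """A synthetic 24-patch reference set (NOT published chart values).

    Eighteen chromatic patches spread over hue at two saturation/value
    levels plus a six-step gray ramp, in row-major chart order.  This is a
    deterministic stand-in so tests and demos never embed licensed chart
    data; real work should pass the published values for the actual chart.
    """
    patches = []
    for i in range(9):
        patches.append(hsv_to_rgb(np.array(i * 20), np.array(200), np.array(220)).astype(float))
    for i in range(9):
        patches.append(hsv_to_rgb(np.array(i * 20 + 10), np.array(120), np.array(150)).astype(float))
    for g in (240, 200, 160, 122, 85, 52):
        patches.append(np.array([g, g, g], dtype=float))
    return np.array(patches)


def make_checker_target(reference: np.ndarray, cast: ColorCorrectionModel | None = None,
                        noise_sd: float = 0.0, seed: int = 0, patch_px: int = 24):
    """Render a 4x6 checker image whose patches are cast(reference) + noise.

    Returns ``(patch_set, image, truth)`` where truth records the injected
    cast and noise.  Measured patch colors are clipped to [0, 255].
    """
    rng = np.random.default_rng(seed)
    reference = np.asarray(reference, dtype=np.float64)
    measured = reference.copy()
    if cast is not None:
        measured = cast.apply_to_colors(measured)
    if noise_sd > 0:
        measured = measured + rng.normal(0.0, noise_sd, size=measured.shape)
    measured = np.clip(measured, 0, 255)
    img = np.zeros((4 * patch_px, 6 * patch_px, 3), dtype=np.uint8)
    for idx in range(24):
        r, c = divmod(idx, 6)
        img[r * patch_px : (r + 1) * patch_px, c * patch_px : (c + 1) * patch_px] = np.round(
            measured[idx]
        ).astype(np.uint8)
    patch_set = PatchSet(measured=measured, reference=reference)
    truth = {"cast": None if cast is None else "affine", "noise_sd": noise_sd, "seed": seed}
    return patch_set, RgbImage(pixels=img, provenance={"format": "synthetic"}), truth


@dataclass
class GridTarget:
    """Dot-grid calibration image with its true point lattice."""

    image: RgbImage
    points_undistorted: np.ndarray  # (N, 2) x, y
    points_distorted: np.ndarray  # (N, 2) x, y (equals undistorted when no model)
    spacing: float
    shape: tuple


def make_grid_target(shape=(900, 1200), spacing: float = 80.0,
                     distortion: DistortionModel | None = None,
                     dot_radius: float = 4.0, margin: float = 40.0,
                     seed: int = 0) -> GridTarget:
    """Dark dot lattice on white, forward-distorted by the given model.

    Dots are rendered with a half-pixel soft edge so intensity-weighted
    centroids recover centers at subpixel accuracy.
    """
    if spacing < 10:
        raise ValueError("spacing must be >= 10 px")
    h, w = shape
    xs = np.arange(margin, w - margin + 1e-9, spacing)
    ys = np.arange(margin, h - margin + 1e-9, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts_u = np.stack([gx.ravel(), gy.ravel()], axis=1)
    pts_d = pts_u if distortion is None else distortion.distort_points(pts_u)

    img = np.full((h, w), 255.0)
    rad = dot_radius
    for x, y in pts_d:
        x0, x1 = int(max(0, math.floor(x - rad - 2))), int(min(w, math.ceil(x + rad + 3)))
        y0, y1 = int(max(0, math.floor(y - rad - 2))), int(min(h, math.ceil(y + rad + 3)))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xx - x, yy - y)
        cov = np.clip(rad + 0.5 - d, 0.0, 1.0)  # soft edge, symmetric about center
        img[y0:y1, x0:x1] = np.minimum(img[y0:y1, x0:x1], 255.0 * (1.0 - cov) + 20.0 * cov)
    rgb = np.repeat(np.round(img).astype(np.uint8)[:, :, None], 3, axis=2)
    return GridTarget(image=RgbImage(pixels=rgb, provenance={"format": "synthetic"}),
                      points_undistorted=pts_u, points_distorted=np.asarray(pts_d),
                      spacing=spacing, shape=shape)


# ---------------------------------------------------------------------------
# factorial study simulation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudyConfig:
    """Design and effect structure for a simulated greenhouse study.

    The default design mirrors a two-greenhouse turf trial: four mowing
    heights (cm) x three irrigation levels (% of actual evapotranspiration
    replacement) assigned to vessels, photographed over eight collection
    dates.  Treatment effects act on the yellow (senescent) fraction; the
    green fraction moves inversely.  Reference covariates are affine
    functions of the fractions with noise; the VQ and NDVI noise SDs are
    solved from ``target_corr_vq``/``target_corr_ndvi`` so the realized
    correlations match the configured targets (VQ rounding variance
    included).
    """

    mowing_heights: tuple = (2.5, 5.0, 7.5, 10.0)
    irrigation_levels: tuple = (100, 65, 30)
    n_dates: int = 8
    lysimeters_per_treatment: int = 6
    n_total: int | None = None  # stratified subsample of the full crossing
    image_replicates: int = 3

    # yellow-fraction model (fractions of ROI area)
    yellow_baseline: float = 0.18
    date_trend: float = 0.22  # total increase across the date range
    irrigation_effects: dict = field(default_factory=lambda: {100: 0.0, 65: 0.04, 30: 0.11})
    mowing_effects: dict = field(
        default_factory=lambda: {2.5: -0.03, 5.0: -0.015, 7.5: 0.02, 10.0: 0.01}
    )
    yellow_noise_sd: float = 0.05
    replicate_noise_sd: float = 0.004  # photo-to-photo within a sample

    # green fraction follows yellow inversely
    green_baseline: float = 0.95
    green_vs_yellow: float = -0.85
    green_noise_sd: float = 0.04

    # covariate links
    vq_intercept: float = 8.6
    vq_slope: float = -9.0  # per unit yellow fraction
    target_corr_vq: float = -0.9
    ndvi_intercept: float = 0.12
    ndvi_slope: float = 0.72  # per unit green fraction
    target_corr_ndvi: float = 0.9
    seed: int = 0


def _noise_sd_for_target(signal_sd: float, slope: float, target_corr: float,
                         extra_var: float = 0.0) -> float:
    """Solve sd(e) so that corr(x, slope*x + e) hits the target magnitude."""
    rho2 = target_corr**2
    total = (slope * signal_sd) ** 2 * (1.0 / rho2 - 1.0)
    return math.sqrt(max(total - extra_var, 1e-12))


def simulate_study(config: SyntheticStudyConfig | None = None, render_scenes: bool = False):
    """Simulate a factorial study table with emulated reference covariates.

    Returns ``(scenes, table)``.  ``table`` has one row per sample
    (vessel x date) with replicate-averaged yellow/green fractions, the
    replicate-level fractions nested in ``rep_yellow``/``rep_green`` list
    columns, and emulated covariates: VQ (1-9, 0.5 steps), NDVI/NDRE in
    [-1, 1], NIR/RED/RE reflectance, clipping production (mg/day) and water
    use (mm/day).  ``scenes`` is empty unless ``render_scenes`` is set (the
    statistics operate on the table; rendering is for image-path tests).
    """
    cfg = config or SyntheticStudyConfig()
    if not cfg.mowing_heights or not cfg.irrigation_levels or cfg.n_dates < 1:
        raise ValueError("empty design")
    rng = np.random.default_rng(cfg.seed)

    rows = []
    dates = np.arange(1, cfg.n_dates + 1)
    for m in cfg.mowing_heights:
        for irr in cfg.irrigation_levels:
            for lys in range(cfg.lysimeters_per_treatment):
                for d in dates:
                    rows.append((m, irr, int(d), lys))
    df = pd.DataFrame(rows, columns=["mowing_height", "irrigation", "date", "lysimeter"])

    if cfg.n_total is not None:
        if cfg.n_total > len(df):
            raise ValueError("n_total exceeds the design size")
        cells = df.groupby(["mowing_height", "irrigation", "date"], sort=False)
        n_cells = cells.ngroups
        base, extra = divmod(cfg.n_total, n_cells)
        if base < 1:
            raise ValueError("n_total too small to keep every cell occupied")
        lucky = rng.choice(n_cells, size=extra, replace=False)
        take = np.full(n_cells, base)
        take[lucky] += 1
        keep_idx = []
        for (_, group), k in zip(cells, take):
            keep_idx.extend(rng.choice(group.index.to_numpy(), size=k, replace=False))
        df = df.loc[sorted(keep_idx)].reset_index(drop=True)

    n = len(df)
    date_frac = (df["date"] - 1) / max(cfg.n_dates - 1, 1)
    yellow = (
        cfg.yellow_baseline
        + cfg.date_trend * date_frac
        + df["irrigation"].map(cfg.irrigation_effects)
        + df["mowing_height"].map(cfg.mowing_effects)
        + rng.normal(0.0, cfg.yellow_noise_sd, n)
    ).clip(lower=0.0)
    green = (
        cfg.green_baseline + cfg.green_vs_yellow * yellow + rng.normal(0.0, cfg.green_noise_sd, n)
    ).clip(lower=0.0)

    # replicate-level photographs of the same sample
    reps_y = yellow.to_numpy()[:, None] + rng.normal(0.0, cfg.replicate_noise_sd,
                                                     (n, cfg.image_replicates))
    reps_g = green.to_numpy()[:, None] + rng.normal(0.0, cfg.replicate_noise_sd,
                                                    (n, cfg.image_replicates))
    yellow_mean = reps_y.mean(axis=1)
    green_mean = reps_g.mean(axis=1)

    # covariates with correlation-calibrated noise
    vq_noise = _noise_sd_for_target(float(np.std(yellow_mean)), cfg.vq_slope,
                                    cfg.target_corr_vq, extra_var=0.25**2 / 12.0)
    vq = cfg.vq_intercept + cfg.vq_slope * yellow_mean + rng.normal(0.0, vq_noise, n)
    vq = np.clip(np.round(vq * 2.0) / 2.0, 1.0, 9.0)  # 0.5-step rating scale

    nd_noise = _noise_sd_for_target(float(np.std(green_mean)), cfg.ndvi_slope,
                                    cfg.target_corr_ndvi)
    ndvi = np.clip(cfg.ndvi_intercept + cfg.ndvi_slope * green_mean
                   + rng.normal(0.0, nd_noise, n), -1.0, 1.0)

    ndre = np.clip(0.05 + 0.45 * green_mean - 0.25 * yellow_mean
                   + rng.normal(0.0, 0.03, n), -1.0, 1.0)
    nir = 0.30 + 0.25 * green_mean + rng.normal(0.0, 0.02, n)
    red = 0.18 - 0.10 * green_mean + 0.06 * yellow_mean + rng.normal(0.0, 0.012, n)
    re = 0.22 - 0.05 * green_mean + 0.05 * yellow_mean + rng.normal(0.0, 0.012, n)
    clipping = np.clip(120.0 + 350.0 * (green_mean - green_mean.mean())
                       + rng.normal(0.0, 35.0, n), 0.0, None)
    water_use = np.clip(4.0 + 3.0 * (green_mean - green_mean.mean())
                        + rng.normal(0.0, 0.8, n), 0.1, None)

    table = df.copy()
    table["sample_id"] = [
        f"m{m}_i{i}_d{d}_l{l}" for m, i, d, l in zip(df["mowing_height"], df["irrigation"],
                                                     df["date"], df["lysimeter"])
    ]
    table["yellow_frac"] = yellow_mean
    table["green_frac"] = green_mean
    table["rep_yellow"] = list(reps_y)
    table["rep_green"] = list(reps_g)
    table["VQ"] = vq
    table["NDVI"] = ndvi
    table["NDRE"] = ndre
    table["NIR"] = nir
    table["RED"] = red
    table["RE"] = re
    table["clipping_mg_day"] = clipping
    table["water_use_mm_day"] = water_use
    table.attrs["config"] = asdict(cfg)
    table.attrs["true_noise"] = {"vq": vq_noise, "ndvi": nd_noise}

    scenes = []
    if render_scenes:
        for i, row in table.iterrows():
            scenes.append(
                make_canopy_scene(
                    green_cover=float(np.clip(row["green_frac"], 0, 1.4)),
                    yellow_cover=float(np.clip(row["yellow_frac"], 0, 1.4)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
    return scenes, table
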