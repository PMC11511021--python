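"""Synthetic scenes, calibration targets, and study-table generators."""

import numpy as np
import pytest

from turfcam.corrections import DistortionModel
from turfcam.segmentation import DEFAULT_RULES
from turfcam.stats import pearson
from turfcam.synthgen import (
    IlluminationModel,
    SyntheticStudyConfig,
    illumination,
    make_canopy_scene,
    make_checker_target,
    make_grid_target,
    simulate_study,
    synthetic_reference_patches,
)


# ---------------------------------------------------------------------------
# illumination drift
# ---------------------------------------------------------------------------


def test_illumination_intercept_and_steady_state():
    assert illumination(0.0) == 16.494
    assert illumination(400.0) == 8.0
    assert illumination(360.0) == 8.0  # floored from t = steady_after on


def test_illumination_prefloor_polynomial_value():
    model = IlluminationModel()
    assert model.polynomial(360.0) == pytest.approx(11.85, abs=1e-9)


def test_illumination_rejects_negative_time_and_accepts_arrays():
    with pytest.raises(ValueError):
        illumination(-1.0)
    out = illumination(np.array([0.0, 100.0, 500.0]))
    assert out.shape == (3,)
    assert out[0] == 16.494 and out[2] == 8.0


# ---------------------------------------------------------------------------
# canopy scenes
# ---------------------------------------------------------------------------


def test_scene_is_pure_function_of_seed():
    a = make_canopy_scene(green_cover=0.4, yellow_cover=0.12, seed=5)
    b = make_canopy_scene(green_cover=0.4, yellow_cover=0.12, seed=5)
    assert np.array_equal(a.image.pixels, b.image.pixels)
    assert np.array_equal(a.labels, b.labels)
    c = make_canopy_scene(green_cover=0.4, yellow_cover=0.12, seed=6)
    assert not np.array_equal(a.image.pixels, c.image.pixels)


def test_zero_coverage_scene_is_blank():
    scene = make_canopy_scene(green_cover=0.0, yellow_cover=0.0, seed=0)
    assert np.all(scene.image.pixels == 255)
    assert all(v == 0 for v in scene.truth["counts"].values())


def test_truth_counts_equal_label_tallies():
    scene = make_canopy_scene(green_cover=0.45, yellow_cover=0.2, seed=9)
    assert scene.truth["label_counts"]["green"] == int(np.sum(scene.labels == 1))
    assert scene.truth["label_counts"]["yellow"] == int(np.sum(scene.labels == 2))


def test_requested_coverage_is_recovered_by_segmentation():
    """Closed loop: generator truth -> thresholds -> fractions within 0.5%."""
    from turfcam.segmentation import segment_image

    # hue range pinned inside the %G band so the request is a %G request
    scene = make_canopy_scene(green_cover=0.59, yellow_cover=0.1, green_hue=(32, 58), seed=3)
    fractions, _ = segment_image(scene.image, roi=scene.roi)
    assert fractions["%G"] == pytest.approx(59.0, abs=0.5)
    assert fractions["%C"] == pytest.approx(59.0, abs=0.5)
    assert fractions["%Y"] == pytest.approx(10.0, abs=0.5)
    # and exactly equal to the per-pixel truth evaluation
    for name in fractions:
        assert fractions[name] == pytest.approx(scene.truth["fractions_pct"][name], abs=0.01)


def test_infeasible_coverage_rejected():
    with pytest.raises(ValueError):
        make_canopy_scene(shape=(80, 80), px_per_mm=0.5, green_cover=1.5, yellow_cover=1.5, seed=0)


def test_illumination_drift_darkens_strokes():
    bright = make_canopy_scene(green_cover=0.4, seed=2, illumination_t=0.0)
    dim = make_canopy_scene(green_cover=0.4, seed=2, illumination_t=400.0)
    assert dim.truth["light_factor"] == pytest.approx(8.0 / 16.494, abs=1e-9)
    v_bright = bright.image.pixels[bright.labels == 1].mean()
    v_dim = dim.image.pixels[dim.labels == 1].mean()
    assert v_dim < v_bright


def test_generated_hsv_lies_strictly_inside_rules():
    scene = make_canopy_scene(green_cover=0.5, yellow_cover=0.2, seed=1)
    from turfcam.colorspace import rgb_to_hsv

    hsv = rgb_to_hsv(scene.image.pixels)
    c_rule = DEFAULT_RULES["%C"]
    on_green = scene.labels == 1
    assert np.all(c_rule.contains(hsv.hue[on_green], hsv.sat[on_green], hsv.val[on_green]))
    y_rule = DEFAULT_RULES["%Y"]
    on_yellow = scene.labels == 2
    assert np.all(y_rule.contains(hsv.hue[on_yellow], hsv.sat[on_yellow], hsv.val[on_yellow]))


# ---------------------------------------------------------------------------
# calibration targets
# ---------------------------------------------------------------------------


def test_checker_identity_cast_zero_noise():
    ref = synthetic_reference_patches()
    patches, image, truth = make_checker_target(ref, cast=None, noise_sd=0.0, seed=0)
    assert np.array_equal(patches.measured, ref)
    assert truth["cast"] is None
    assert image.pixels.shape == (4 * 24, 6 * 24, 3)


def test_checker_noise_has_configured_spread():
    ref = synthetic_reference_patches()
    devs = []
    for seed in range(50):  # 50 x 24 patches x 3 channels
        patches, _, _ = make_checker_target(ref, cast=None, noise_sd=2.0, seed=seed)
        devs.append(patches.measured - ref)
    sd = float(np.std(np.concatenate(devs)))
    assert sd == pytest.approx(2.0, abs=0.3)


def test_grid_target_lattice_counts():
    target = make_grid_target(shape=(600, 800), spacing=40.0, seed=0)
    n = len(target.points_undistorted)
    assert n == 19 * 14


def test_grid_target_forward_distortion_matches_analytic_map():
    barrel = DistortionModel(center=(399.5, 299.5), radial_coeffs=[1.0, 0.0, -2e-8])
    target = make_grid_target(shape=(600, 800), spacing=40.0, distortion=barrel, seed=0)
    p = target.points_undistorted - np.array(barrel.center)
    r_u = np.hypot(p[:, 0], p[:, 1])
    r_d = r_u * (1.0 - 2e-8 * r_u**2)
    expected = p * np.where(r_u > 0, r_d / np.where(r_u > 0, r_u, 1), 1.0)[:, None] + barrel.center
    assert float(np.abs(expected - target.points_distorted).max()) < 0.5
    # corners move inward under a barrel model
    corner = np.argmax(r_u)
    assert np.hypot(*(target.points_distorted[corner] - barrel.center)) < r_u[corner]


def test_grid_target_requires_sane_spacing():
    with pytest.raises(ValueError):
        make_grid_target(spacing=5.0)


# ---------------------------------------------------------------------------
# study simulation
# ---------------------------------------------------------------------------


def test_simulate_study_shape_and_ranges():
    cfg = SyntheticStudyConfig(seed=1)
    scenes, table = simulate_study(cfg)
    assert scenes == []
    assert len(table) == 4 * 3 * 8 * cfg.lysimeters_per_treatment
    assert table["VQ"].between(1, 9).all()
    assert table["NDVI"].between(-1, 1).all()
    assert set(table["mowing_height"]) == {2.5, 5.0, 7.5, 10.0}
    assert set(table["irrigation"]) == {100, 65, 30}
    assert table["date"].nunique() == 8


def test_simulate_study_deterministic():
    _, a = simulate_study(SyntheticStudyConfig(seed=4))
    _, b = simulate_study(SyntheticStudyConfig(seed=4))
    assert a.drop(columns=["rep_yellow", "rep_green"]).equals(
        b.drop(columns=["rep_yellow", "rep_green"])
    )


def test_simulate_study_empty_design_rejected():
    with pytest.raises(ValueError):
        simulate_study(SyntheticStudyConfig(mowing_heights=(), seed=0))


def test_stratified_subsample_keeps_cells_occupied():
    cfg = SyntheticStudyConfig(n_total=316, seed=2)
    _, table = simulate_study(cfg)
    assert len(table) == 316
    sizes = table.groupby(["mowing_height", "irrigation", "date"]).size()
    assert sizes.min() >= 3 and sizes.max() <= 4 and len(sizes) == 96


def test_realized_correlations_hit_configured_targets():
    cfg = SyntheticStudyConfig(n_total=316, seed=0)
    _, table = simulate_study(cfg)
    r_vq, _ = pearson(table["yellow_frac"], table["VQ"])
    r_nd, _ = pearson(table["green_frac"], table["NDVI"])
    assert r_vq == pytest.approx(-0.9, abs=0.04)
    assert r_nd == pytest.approx(0.9, abs=0.04)


def test_treatment_effects_converge_with_replication():
    """Realized date trend approaches the configured effect at 10x replication."""
    cfg = SyntheticStudyConfig(lysimeters_per_treatment=60, seed=8)
    _, table = simulate_study(cfg)
    date_frac = (table["date"] - 1) / (cfg.n_dates - 1)
    slope = np.polyfit(date_frac, table["yellow_frac"], 1)[0]
    assert slope == pytest.approx(cfg.date_trend, rel=0.10)
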