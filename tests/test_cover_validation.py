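import numpy as np
import pytest

from furrowscan import cover_validation as cv
from furrowscan.errors import NoThresholdError, ParameterError


class TestEquisolid:
    @pytest.mark.parametrize("theta, f, expected", [
        (0.0, 8.0, 0.0),
        (90.0, 8.0, 11.3137),
        (180.0, 8.0, 16.0),  # hemisphere rim at 2f
    ])
    def test_projection_values(self, theta, f, expected):
        assert cv.equisolid_radius(theta, f) == pytest.approx(expected, abs=1e-4)

    def test_negative_focal_length_rejected(self):
        with pytest.raises(ParameterError):
            cv.equisolid_radius(30.0, -1.0)

    def test_strictly_increasing_on_hemisphere(self):
        th = np.linspace(0, 90, 200)
        r = cv.equisolid_radius(th, 8.0)
        assert np.all(np.diff(r) > 0)


class TestPlotCropping:
    def test_nadir_maps_to_image_center(self):
        model = cv.FisheyeModel()
        px, py = cv.ground_to_pixel(model, 0.0, 0.0)
        assert (px, py) == model.image_center

    def test_corner_two_step_trig_oracle(self):
        model = cv.FisheyeModel(f=8.0, camera_height_m=2.8)
        gx, gy = 1.83, 0.76
        px, py = cv.ground_to_pixel(model, gx, gy)
        # independent oracle: direct trig
        rho = np.hypot(gx, gy)
        theta = np.degrees(np.arctan(rho / 2.8))
        r = 2 * 8.0 * np.sin(np.radians(theta) / 2) * model.pixels_per_unit_r
        assert np.hypot(px - model.image_center[0],
                        py - model.image_center[1]) == pytest.approx(r, rel=1e-9)
        assert theta == pytest.approx(35.28, abs=0.05)

    def test_pixel_ground_round_trip(self):
        model = cv.FisheyeModel()
        gx = np.array([0.0, 0.5, -1.2, 1.83])
        gy = np.array([0.0, -0.3, 0.7, 0.76])
        px, py = cv.ground_to_pixel(model, gx, gy)
        gx2, gy2 = cv.pixel_to_ground(model, px, py)
        assert np.allclose(gx2, gx, atol=1e-9)
        assert np.allclose(gy2, gy, atol=1e-9)

    def test_crop_contains_plot_and_clips(self):
        model = cv.FisheyeModel()
        img = np.zeros((400, 400, 3), dtype=np.uint8)
        crop = cv.crop_to_plot(img, model, (-1.83, 1.83, -0.76, 0.76))
        assert 0 < crop.shape[0] < 400
        assert 0 < crop.shape[1] < 400
        with pytest.raises(ParameterError):
            cv.crop_to_plot(img, model, (0.0, 0.0, -0.1, 0.1))
        with pytest.warns(UserWarning):
            cv.crop_to_plot(img, model, (-60.0, 60.0, -60.0, 60.0))


class TestGndvi:
    def test_equal_bands_give_zero(self):
        r = np.full((4, 4), 0.4)
        assert np.allclose(cv.gndvi(r, r), 0.0)

    def test_arithmetic_example(self):
        out = cv.gndvi(np.array([[0.2]]), np.array([[0.6]]))
        assert out[0, 0] == pytest.approx(0.5)

    def test_bounds_and_missing(self):
        red = np.array([[0.0, 0.3, 0.0]])
        green = np.array([[0.7, 0.0, 0.0]])
        out = cv.gndvi(red, green)
        assert out[0, 0] == 1.0
        assert out[0, 1] == -1.0
        assert np.isnan(out[0, 2])
        rng = np.random.default_rng(0)
        out = cv.gndvi(rng.uniform(0, 255, (50, 50)),
                       rng.uniform(0, 255, (50, 50)))
        assert np.nanmax(out) <= 1.0 and np.nanmin(out) >= -1.0

    def test_shape_mismatch(self):
        with pytest.raises(ParameterError):
            cv.gndvi(np.zeros((2, 2)), np.zeros((3, 3)))


def brute_force_valley(counts, edges, smooth_window=5):
    """Independent oracle: scan every interior bin between the two highest
    smoothed modes (cumulative-sum smoothing, not convolution)."""
    counts = np.asarray(counts, dtype=float)
    half = smooth_window // 2
    padded = np.concatenate([np.zeros(half), counts, np.zeros(half)])
    cs = np.concatenate([[0.0], np.cumsum(padded)])
    sm = (cs[smooth_window:] - cs[:-smooth_window]) / smooth_window
    order = np.argsort(sm)[::-1]
    modes = []
    for i in order:
        if 0 < i < len(sm) - 1 and sm[i] >= sm[i - 1] and sm[i] >= sm[i + 1] \
                and (sm[i] > sm[i - 1] or sm[i] > sm[i + 1]):
            if all(abs(i - j) > 1 for j in modes):
                modes.append(i)
        if len(modes) == 2:
            break
    lo, hi = sorted(modes)
    best = min(range(lo + 1, hi), key=lambda i: (sm[i], i))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers[best]


class TestBimodalThreshold:
    def test_forced_valley(self):
        counts = np.array([9, 1, 8])
        edges = np.array([0.0, 1.0, 2.0, 3.0])
        thr = cv.bimodal_threshold(counts, edges, smooth_window=1)
        assert thr == pytest.approx(1.5)  # center of the middle bin

    def test_tie_resolves_to_lower_bin(self):
        counts = np.array([9, 2, 5, 2, 8], dtype=float)
        edges = np.linspace(0, 5, 6)
        thr = cv.bimodal_threshold(counts, edges, smooth_window=1)
        assert thr == pytest.approx(1.5)  # first of the two tied valleys

    def test_normal_mixture_matches_brute_force(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(-0.3, 0.05, 20000),
                               rng.normal(0.4, 0.05, 20000)])
        counts, edges = np.histogram(vals, bins=256, range=(-1, 1))
        thr = cv.bimodal_threshold(counts, edges)
        assert thr == pytest.approx(brute_force_valley(counts, edges))
        assert -0.1 < thr < 0.2

    def test_unimodal_raises(self):
        rng = np.random.default_rng(5)
        counts, edges = np.histogram(rng.normal(0, 0.1, 5000), bins=256,
                                     range=(-1, 1))
        with pytest.raises(NoThresholdError):
            cv.bimodal_threshold(counts, edges)

    def test_invariant_to_count_scaling(self):
        rng = np.random.default_rng(6)
        vals = np.concatenate([rng.normal(-0.4, 0.06, 5000),
                               rng.normal(0.3, 0.06, 5000)])
        counts, edges = np.histogram(vals, bins=256, range=(-1, 1))
        assert cv.bimodal_threshold(counts, edges) == \
            cv.bimodal_threshold(counts * 7, edges)


class TestFractionalCover:
    def test_extremes_and_half(self):
        img = np.full((10, 10), 0.5)
        assert cv.fractional_cover(img, 0.0) == 1.0
        assert cv.fractional_cover(img, 0.6) == 0.0
        half = np.concatenate([np.full(50, -0.5), np.full(50, 0.5)])
        assert cv.fractional_cover(half, 0.0) == 0.5

    def test_all_missing_rejected(self):
        with pytest.raises(ParameterError):
            cv.fractional_cover(np.full((3, 3), np.nan), 0.0)


class TestRenderer:
    def test_zero_cover_is_pure_soil_and_unimodal(self):
        model = cv.FisheyeModel()
        img, mask, painted = cv.render_plot_image(0.0, model, seed=1)
        assert painted == 0.0
        assert not mask.any()
        est = cv.estimate_cover(img)
        assert est.threshold_is_fallback
        assert est.green_fraction < 0.01

    def test_full_cover_estimates_near_one(self):
        model = cv.FisheyeModel()
        img, mask, painted = cv.render_plot_image(1.0, model, seed=2)
        assert painted > 0.98
        crop = cv.crop_to_plot(img, model, (-1.83, 1.83, -0.76, 0.76))
        est = cv.estimate_cover(crop)
        assert est.green_fraction > 0.95

    def test_same_seed_identical_image(self):
        model = cv.FisheyeModel()
        a, _, _ = cv.render_plot_image(0.4, model, seed=3)
        b, _, _ = cv.render_plot_image(0.4, model, seed=3)
        assert np.array_equal(a, b)

    def test_estimator_within_003_of_painted_truth(self):
        model = cv.FisheyeModel()
        extent = (-1.83, 1.83, -0.76, 0.76)
        for target, seed in [(0.15, 10), (0.4, 11), (0.7, 12)]:
            img, mask, _ = cv.render_plot_image(target, model, seed=seed)
            crop = cv.crop_to_plot(img, model, extent)
            est = cv.estimate_cover(crop)
            truth = cv.crop_to_plot(mask[..., None], model, extent).mean()
            assert est.green_fraction == pytest.approx(truth, abs=0.03)


class TestImageIO:
    def test_png_round_trip(self, tmp_path):
        model = cv.FisheyeModel(image_center=(32.0, 32.0),
                                pixels_per_unit_r=5.0)
        img, _, _ = cv.render_plot_image(0.3, model, seed=7,
                                         image_size=(64, 64))
        path = tmp_path / "plot.png"
        cv.save_rgb(img, path)
        back = cv.load_rgb(path)
        assert np.array_equal(back, img)


class TestValidate:
    def test_identical_vectors(self):
        x = np.array([0.1, 0.5, 0.9, 1.2])
        res = cv.validate(x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.rmse == 0.0

    def test_rmse_separates_from_r2(self):
        x = np.array([0.2, 0.4, 0.6, 0.8])
        res = cv.validate(2 * x, x)
        assert res.r2 == pytest.approx(1.0)
        assert res.rmse == pytest.approx(np.sqrt(np.mean(x**2)))

    def test_five_point_ols_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 2.9, 4.2, 4.8, 6.1])
        res = cv.validate(y, x)
        # closed-form OLS
        b = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean())**2)
        a = y.mean() - b * x.mean()
        assert res.slope == pytest.approx(b)
        assert res.intercept == pytest.approx(a)
        r = np.corrcoef(x, y)[0, 1]
        assert res.r2 == pytest.approx(r**2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError):
            cv.validate([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ParameterError):
            cv.validate([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestEndToEndCoverValidation:
    def test_image_cover_r2_against_truth(self):
        """75 rendered plots spanning cover 0.05-0.9: image estimates track
        painted truth with r² ≥ 0.95."""
        model = cv.FisheyeModel(image_center=(150.0, 150.0),
                                pixels_per_unit_r=23.0)
        extent = (-1.83, 1.83, -0.76, 0.76)
        targets = np.linspace(0.05, 0.9, 75)
        truths, ests = [], []
        for i, target in enumerate(targets):
            img, mask, _ = cv.render_plot_image(
                target, model, seed=100 + i, image_size=(300, 300))
            crop = cv.crop_to_plot(img, model, extent)
            est = cv.estimate_cover(crop)
            truths.append(cv.crop_to_plot(mask[..., None], model,
                                          extent).mean())
            ests.append(est.green_fraction)
        res = cv.validate(np.array(ests), np.array(truths))
        assert res.r2 >= 0.95
        assert res.rmse <= 0.03
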