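"""Per-nodule tables, wide-field integrated density, and the calibration fit."""

import numpy as np
import pandas as pd
import pytest

from lungtam import (
    CalibrationModel,
    CellDetections,
    ImageVolume,
    NoduleLabelMap,
    SimulationConfig,
    UndefinedStatisticError,
    compute_tam_density,
    compute_tumor_burden,
    fit_calibration,
    generate_lung_volume,
    infer_density_from_widefield,
    nodule_signal_correlations,
    widefield_integrated_density,
)


def cube_label_map(n_voxels=1000, voxel=5.0):
    """A single 10x10x10 nodule of `n_voxels` labeled voxels."""
    side = int(round(n_voxels ** (1 / 3)))
    labels = np.zeros((side + 4, side + 4, side + 4), np.int32)
    labels[2:2 + side, 2:2 + side, 2:2 + side] = 1
    return NoduleLabelMap(labels, (voxel,) * 3)


def detections_at(points_um):
    pts = np.asarray(points_um, float).reshape(-1, 3)
    return CellDetections(pts, pd.DataFrame(index=range(len(pts))))


class TestBurden:
    def test_empty_map_zero_burden(self):
        lm = NoduleLabelMap(np.zeros((4, 4, 4), np.int32), (5, 5, 5))
        res = compute_tumor_burden(lm)
        assert res.total_mm3 == 0.0 and res.n_nodules == 0

    def test_thousand_voxels_at_5um_pitch(self):
        res = compute_tumor_burden(cube_label_map(1000, 5.0))
        assert res.total_mm3 == pytest.approx(1.25e-4)  # 1000 * 125 µm³

    def test_burden_tracks_ground_truth(self, segmented_small_lung):
        _, truth, label_map, _ = segmented_small_lung
        res = compute_tumor_burden(label_map)
        true_total = truth.nodules_frame().volume_mm3.sum()
        assert res.total_mm3 == pytest.approx(true_total, rel=0.15)


class TestTamDensity:
    def test_no_detections_zero_density(self):
        lm = cube_label_map()
        table = compute_tam_density(lm, detections_at(np.empty((0, 3))))
        assert (table.tam_density_mm3 == 0).all()

    def test_seventeen_cells_in_a_milli_cubed(self):
        lm = cube_label_map(1000, 10.0)  # 1000 * 1000 µm³ = 1e-3 mm³
        center = np.full(3, 7 * 10.0)
        pts = center + np.random.default_rng(0).uniform(-20, 20, (17, 3))
        table = compute_tam_density(lm, detections_at(pts))
        assert table.tam_count.iloc[0] == 17
        assert table.tam_density_mm3.iloc[0] == pytest.approx(17_000.0)

    def test_density_times_volume_recovers_count_exactly(self, segmented_small_lung):
        _, _, label_map, detections = segmented_small_lung
        table = compute_tam_density(label_map, detections)
        np.testing.assert_allclose(
            table.tam_density_mm3 * table.volume_mm3, table.tam_count, rtol=1e-9
        )

    def test_detection_outside_extent_names_the_point(self):
        lm = cube_label_map()
        with pytest.raises(ValueError, match="outside"):
            compute_tam_density(lm, detections_at([1e5, 1.0, 1.0]))

    def test_background_detections_counted_peritumoral(self):
        lm = cube_label_map(1000, 5.0)
        pts = [[1.0, 1.0, 1.0], [30.0, 30.0, 30.0]]  # outside / inside nodule
        table = compute_tam_density(lm, detections_at(pts))
        assert table.attrs["n_peritumoral"] == 1
        assert table.tam_count.iloc[0] == 1


class TestWidefieldDensity:
    def _image(self, arr, pixel=1.0):
        return ImageVolume({"tam_np": np.asarray(arr, np.float32)}, (pixel, pixel))

    def test_uniform_image_zero_density(self):
        img = self._image(np.full((20, 20), 3.0))
        feet = np.zeros((20, 20), int)
        feet[5:10, 5:10] = 1
        df = widefield_integrated_density(img, feet)
        assert df.integrated_density.iloc[0] == 0.0

    def test_flat_excess_equals_its_height(self):
        arr = np.full((20, 20), 5.0)
        feet = np.zeros((20, 20), int)
        feet[4:14, 4:14] = 1  # 100 px footprint
        arr[4:14, 4:14] += 10.0
        df = widefield_integrated_density(self._image(arr), feet)
        assert df.integrated_density.iloc[0] == pytest.approx(10.0)
        assert df.footprint_area_um2.iloc[0] == pytest.approx(100.0)

    def test_footprint_grid_mismatch_rejected(self):
        img = self._image(np.zeros((10, 10)))
        with pytest.raises(ValueError, match="footprint"):
            widefield_integrated_density(img, np.zeros((4, 4), int))


class TestCalibration:
    def test_exact_proportionality(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        model = fit_calibration(x, 2 * x)
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == 0.0
        assert model.pearson_r == pytest.approx(1.0)

    def test_free_intercept_matches_hand_ols(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 3.0, 5.0, 4.0, 6.0])
        # closed-form OLS oracle
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        model = fit_calibration(x, y, mode="free_intercept")
        assert model.slope == pytest.approx(slope)
        assert model.intercept == pytest.approx(intercept)

    def test_too_few_or_degenerate_pairs(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_calibration([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(UndefinedStatisticError):
            fit_calibration([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_inference_through_origin(self):
        model = CalibrationModel(2.0, 0.0, 1.0, 5)
        out = infer_density_from_widefield(model, np.array([5.0, 0.0]))
        np.testing.assert_allclose(out, [10.0, 0.0])

    def test_negative_predictions_clip_with_warning(self):
        model = CalibrationModel(2.0, -10.0, 0.9, 5, mode="free_intercept")
        with pytest.warns(UserWarning, match="clipped"):
            out = infer_density_from_widefield(model, np.array([1.0]))
        assert out[0] == 0.0

    def test_unfitted_model_rejected(self):
        model = CalibrationModel(float("nan"), 0.0, 0.0, 0)
        with pytest.raises(ValueError, match="not fitted"):
            infer_density_from_widefield(model, np.array([1.0]))

    def test_slope_recovers_generative_constant_as_noise_vanishes(self):
        rng = np.random.default_rng(4)
        counts = np.exp(rng.uniform(np.log(50), np.log(5000), 40))
        c = 0.01
        errors = []
        for noise in (0.10, 0.01):
            density = c * counts * (1 + noise * rng.normal(size=40))
            model = fit_calibration(density, counts)
            errors.append(abs(model.slope - 1 / c) / (1 / c))
        assert errors[1] < errors[0]
        assert errors[1] < 0.02

    def test_intensity_scaling_moves_slope_inversely(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(1, 10, 20)
        y = 3 * x * (1 + 0.05 * rng.normal(size=20))
        m1 = fit_calibration(x, y)
        m2 = fit_calibration(10 * x, y)
        assert m2.slope == pytest.approx(m1.slope / 10)
        assert m2.pearson_r == pytest.approx(m1.pearson_r)


class TestSignalCorrelations:
    def test_channel_against_itself(self):
        df = pd.DataFrame(dict(a=[1.0, 2.0, 3.0, 5.0]))
        df["b"] = df.a
        res = nodule_signal_correlations(df, "a", "b")
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_collinear_points_exactly_one(self):
        df = pd.DataFrame(dict(x=[1.0, 2.0, 3.0], y=[2.0, 4.0, 6.0]))
        res = nodule_signal_correlations(df, "x", "y")
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_signaled(self):
        df = pd.DataFrame(dict(x=[1.0, 1.0, 1.0], y=[1.0, 2.0, 3.0]))
        with pytest.raises(UndefinedStatisticError):
            nodule_signal_correlations(df, "x", "y")

    def test_drug_tracks_carrier_in_cogenerated_field(self):
        # carrier and drug channels share per-nodule levels up to 5% noise,
        # mirroring dual-labelled nanoparticle delivery readouts
        cfg = SimulationConfig(
            field_size_um=(500.0, 1000.0, 1000.0), n_nodules=6,
            nodule_radius_range_um=(70.0, 140.0), include_drug_channels=True,
            snr=20.0, seed=31,
        )
        volume, truth = generate_lung_volume(cfg)
        from lungtam import detect_cells, segment_nodules

        label_map = segment_nodules(volume, "nuclear")
        table = compute_tam_density(
            label_map, detect_cells(volume, "tam_np"), volume
        )
        res = nodule_signal_correlations(table, "carrier_mean", "drug_mean")
        assert res.r_squared >= 0.94
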