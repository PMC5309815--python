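"""Generator contracts: geometry, TAM placement statistics, determinism,
and the wide-field rendering."""

import numpy as np
import pytest

from lungtam import (
    ImageVolume,
    Nodule,
    SimulationConfig,
    generate_lung_volume,
    place_tam,
    render_widefield,
)
from lungtam.synthetic import NodulePlacementError, _stream


def sphere(radius_um: float, center=None) -> Nodule:
    center = np.full(3, 500.0) if center is None else np.asarray(center, float)
    return Nodule(1, center, np.full(3, radius_um), np.eye(3))


class TestPlaceTam:
    def test_zero_density_gives_empty_point_set(self):
        pts = place_tam(sphere(100), 0.0, rng=np.random.default_rng(0))
        assert pts.shape == (0, 3)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            place_tam(sphere(100), -1.0)

    def test_poisson_mean_matches_density_times_volume(self):
        # 620 µm radius sphere has volume ~0.998 mm^3, so at the study's
        # average density of 17,000 mm^-3 the mean count must sit at
        # density * volume within 3 standard errors over 200 replicates
        nod = sphere(620.0, center=(700, 700, 700))
        rng = np.random.default_rng(11)
        counts = [len(place_tam(nod, 17_000.0, rng=rng)) for _ in range(200)]
        expected = 17_000.0 * nod.volume_mm3
        se = np.sqrt(expected / 200)
        assert abs(np.mean(counts) - expected) < 3 * se

    @pytest.mark.parametrize("mode,bias", [("uniform", 0), ("rim", 4), ("core", 3)])
    def test_all_points_inside_ellipsoid(self, mode, bias):
        nod = Nodule(
            1, np.array([300.0, 400.0, 500.0]), np.array([80.0, 120.0, 100.0]),
            np.linalg.qr(np.random.default_rng(3).normal(size=(3, 3)))[0],
        )
        pts = place_tam(nod, 50_000.0, mode, bias, np.random.default_rng(5))
        assert len(pts) > 100
        assert nod.contains(pts).all()

    def test_rim_bias_concentrates_points_outward(self):
        # uniform placement puts 1 - 0.8^3 = 48.8% of points beyond r=0.8;
        # rim bias 4 must exceed that analytic fraction
        nod = sphere(100.0)
        rng = np.random.default_rng(2)
        pts = place_tam(nod, 300_000.0, "rim", 4.0, rng)
        r = np.linalg.norm((pts - nod.center_um) / nod.semi_axes_um, axis=1)
        assert (r > 0.8).mean() > 1 - 0.8**3

    def test_core_bias_concentrates_points_inward(self):
        nod = sphere(100.0)
        pts = place_tam(nod, 300_000.0, "core", 3.0, np.random.default_rng(2))
        r = np.linalg.norm((pts - nod.center_um) / nod.semi_axes_um, axis=1)
        assert (r < 0.5).mean() > 0.125  # uniform fraction below r=0.5


class TestGenerateLungVolume:
    def test_zero_nodules_is_pure_background(self):
        cfg = SimulationConfig(
            field_size_um=(200, 200, 200), n_nodules=0, snr=None, seed=0
        )
        volume, truth = generate_lung_volume(cfg)
        assert truth.nodules == []
        assert len(truth.cells) == 0
        np.testing.assert_allclose(
            volume.channel("nuclear"), cfg.nuclear_background
        )
        assert volume.channel("tumor_reporter").max() == 0

    def test_ground_truth_has_requested_nodule_count(self, small_lung):
        (volume, truth), cfg = small_lung
        assert len(truth.nodules) == cfg.n_nodules == 5
        assert set(truth.cells.nodule_id) <= {n.id for n in truth.nodules}

    def test_nuclear_contrast_survives_blur_and_noise(self, small_lung):
        (volume, truth), cfg = small_lung
        nuclear = volume.channel("nuclear")
        bg = cfg.nuclear_background
        for nod in truth.nodules:
            sl, mask = nod.rasterize(volume.shape, volume.voxel_size)
            inside_mean = nuclear[sl][mask].mean()
            assert inside_mean - bg >= 0.8 * (cfg.nodule_contrast - 1) * bg

    def test_default_densities_span_reported_range(self, small_lung):
        (volume, truth), _ = small_lung
        d = truth.nodules_frame().tam_density_mm3
        # realized (Poisson) densities can leak slightly past the seeded range
        assert (d > 7_000).all() and (d < 65_000).all()

    def test_identical_seed_bit_identical_output(self):
        cfg = SimulationConfig(
            field_size_um=(300, 400, 400), n_nodules=2,
            nodule_radius_range_um=(60, 100), seed=13,
        )
        va, ta = generate_lung_volume(cfg)
        vb, tb = generate_lung_volume(cfg)
        for name in va.channel_names:
            np.testing.assert_array_equal(va.channel(name), vb.channel(name))
        assert ta.nodules_frame().equals(tb.nodules_frame())
        assert ta.cells.equals(tb.cells)

    def test_reporter_support_is_voxelized_ellipsoid_union(self, clean_sphere):
        volume, truth = clean_sphere
        support = volume.channel("tumor_reporter") > 0
        expect = np.zeros(volume.shape, bool)
        for nod in truth.nodules:
            sl, mask = nod.rasterize(volume.shape, volume.voxel_size)
            expect[sl] |= mask
        np.testing.assert_array_equal(support, expect)

    def test_true_volume_matches_ellipsoid_formula(self, small_lung):
        (volume, truth), _ = small_lung
        for nod in truth.nodules:
            a, b, c = nod.semi_axes_um
            assert nod.volume_mm3 == pytest.approx(
                4 / 3 * np.pi * a * b * c / 1e9, rel=1e-12
            )

    def test_cells_lie_inside_parent_nodule(self, small_lung):
        (volume, truth), _ = small_lung
        for nod in truth.nodules:
            pts = truth.cell_positions_um(nod.id)
            assert nod.contains(pts).all()

    def test_density_times_volume_equals_count(self, small_lung):
        (volume, truth), _ = small_lung
        for nod in truth.nodules:
            assert nod.tam_density_mm3 * nod.volume_mm3 == pytest.approx(
                nod.tam_count, rel=1e-9
            )

    def test_crowded_field_raises_naming_the_nodule(self):
        cfg = SimulationConfig(
            field_size_um=(550, 550, 550), n_nodules=8,
            nodule_radius_range_um=(150, 180), max_placement_tries=20, seed=0,
        )
        with pytest.raises(NodulePlacementError, match="nodule"):
            generate_lung_volume(cfg)

    def test_count_calibration_unbiased_over_many_nodules(self):
        # realized count / true volume estimates the seeded density to 5%
        # over >= 100 nodules
        density = 20_000.0
        total_count, total_vol = 0, 0.0
        for i in range(120):
            nod = sphere(150.0, center=(200, 200, 200))
            pts = place_tam(nod, density, rng=_stream(1000 + i, 0))
            total_count += len(pts)
            total_vol += nod.volume_mm3
        assert total_count / total_vol == pytest.approx(density, rel=0.05)


class TestRenderWidefield:
    def test_constant_volume_projects_to_constant(self):
        vol = ImageVolume(
            {"c": np.full((8, 40, 40), 7.0, np.float32)}, (5, 5, 5)
        )
        wf = render_widefield(vol, downsample_factor=2, blur_sigma_um=8.0)
        np.testing.assert_allclose(wf.channel("c"), 7.0, rtol=1e-6)
        assert wf.voxel_size == (10.0, 10.0)

    def test_identity_configuration_equals_max_projection(self):
        rng = np.random.default_rng(0)
        arr = rng.random((6, 20, 20)).astype(np.float32)
        vol = ImageVolume({"c": arr}, (5, 4, 4))
        wf = render_widefield(vol, downsample_factor=1, blur_sigma_um=0.0)
        np.testing.assert_array_equal(wf.channel("c"), arr.max(axis=0))

    def test_single_voxel_mass_is_conserved_by_blur(self):
        arr = np.zeros((5, 41, 41), np.float32)
        arr[2, 20, 20] = 100.0
        vol = ImageVolume({"c": arr}, (5, 5, 5))
        wf = render_widefield(vol, downsample_factor=1, blur_sigma_um=10.0)
        assert wf.channel("c").sum() == pytest.approx(100.0, rel=1e-3)

    def test_downsample_below_one_rejected(self):
        vol = ImageVolume({"c": np.zeros((2, 8, 8), np.float32)}, (5, 5, 5))
        with pytest.raises(ValueError):
            render_widefield(vol, downsample_factor=0)
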