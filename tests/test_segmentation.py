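"""Segmentation and spot-detection contracts, with analytic geometry oracles."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from lungtam import (
    ImageVolume,
    NoduleLabelMap,
    SegmentationParams,
    SimulationConfig,
    UndefinedStatisticError,
    detect_cells,
    generate_lung_volume,
    segment_nodules,
    segmentation_concordance,
)
from lungtam.synthetic import render_puncta


def puncta_volume(points_um, shape=(80, 80, 80), voxel=2.5, peak=100.0,
                  noise_sigma=0.0, seed=0, background=50.0):
    """Render puncta of 5 µm radius with optional Gaussian noise."""
    img = background + render_puncta(
        shape, (voxel,) * 3, np.asarray(points_um, float), peak, 2.5,
        (1.5, 1.0, 1.0),
    )
    if noise_sigma:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(size=shape) * noise_sigma, 0, None)
    return ImageVolume({"spots": img.astype(np.float32)}, (voxel,) * 3)


class TestSegmentNodules:
    def test_constant_background_yields_empty_map(self):
        vol = ImageVolume({"nuclear": np.full((20, 20, 20), 5.0, np.float32)},
                          (5, 5, 5))
        lm = segment_nodules(vol, "nuclear")
        assert lm.n_nodules == 0

    def test_missing_channel_raises(self):
        vol = ImageVolume({"nuclear": np.zeros((4, 4, 4), np.float32)}, (5, 5, 5))
        with pytest.raises(KeyError, match="tam_np"):
            segment_nodules(vol, "tam_np")

    def test_single_sphere_volume_within_15pct_of_analytic(self):
        cfg = SimulationConfig(
            field_size_um=(400, 400, 400), n_nodules=1,
            nodule_radius_range_um=(100, 100), axis_ratio_range=(1.0, 1.0),
            snr=10.0, tam_density_range_mm3=(0.0, 0.0), seed=3,
        )
        volume, _ = generate_lung_volume(cfg)
        lm = segment_nodules(volume, "nuclear")
        assert lm.n_nodules == 1
        analytic = 4 / 3 * np.pi * 0.1**3  # (4/3) pi (0.1 mm)^3
        assert lm.volumes_mm3()[1] == pytest.approx(analytic, rel=0.15)

    def test_well_separated_spheres_stay_distinct(self):
        cfg = SimulationConfig(
            field_size_um=(500, 1000, 1000), n_nodules=2,
            nodule_radius_range_um=(90, 110), snr=10.0,
            tam_density_range_mm3=(0.0, 0.0), placement_margin_um=60.0, seed=1,
        )
        volume, truth = generate_lung_volume(cfg)
        centers = np.array([n.center_um for n in truth.nodules])
        assert np.linalg.norm(centers[0] - centers[1]) > 220 + 4 * 4.0
        lm = segment_nodules(volume, "nuclear")
        assert lm.n_nodules == 2

    def test_volume_conservation_on_clean_voxelized_ellipsoid(self, clean_sphere):
        # no blur, no noise: the segmented mask must equal the rasterized
        # ellipsoid voxel-for-voxel
        volume, truth = clean_sphere
        params = SegmentationParams(smoothing_sigma_um=0.0)
        lm = segment_nodules(volume, "nuclear", params)
        sl, mask = truth.nodules[0].rasterize(volume.shape, volume.voxel_size)
        assert lm.n_nodules == 1
        assert (lm.labels[sl][mask] == 1).all()
        assert (lm.labels > 0).sum() == mask.sum()

    def test_min_volume_filter_is_monotone(self, small_lung):
        (volume, _), _ = small_lung
        counts = []
        for mv in (0.0, 2e-5, 2e-4, 2e-3, 2e-2):
            params = SegmentationParams(min_nodule_volume_mm3=mv)
            counts.append(segment_nodules(volume, "nuclear", params).n_nodules)
        assert counts == sorted(counts, reverse=True)

    def test_anisotropic_sampling_preserves_volume(self):
        kw = dict(
            field_size_um=(400.0, 400.0, 400.0), n_nodules=1,
            nodule_radius_range_um=(100.0, 100.0), axis_ratio_range=(1.0, 1.0),
            random_orientation=False, snr=20.0,
            tam_density_range_mm3=(0.0, 0.0), seed=5,
        )
        iso, _ = generate_lung_volume(
            SimulationConfig(voxel_size_um=(5.0, 5.0, 5.0), **kw)
        )
        aniso, _ = generate_lung_volume(
            SimulationConfig(voxel_size_um=(10.0, 5.0, 5.0), **kw)
        )
        v_iso = segment_nodules(iso, "nuclear").volumes_mm3()[1]
        v_aniso = segment_nodules(aniso, "nuclear").volumes_mm3()[1]
        assert v_aniso == pytest.approx(v_iso, rel=0.10)


class TestDetectCells:
    def test_constant_channel_yields_no_detections(self):
        vol = ImageVolume({"spots": np.zeros((20, 20, 20), np.float32)}, (3, 3, 3))
        assert len(detect_cells(vol, "spots")) == 0

    def test_isolated_puncta_found_within_2um(self):
        rng = np.random.default_rng(8)
        # 20 well-separated puncta on a jittered grid, SNR 10
        grid = np.stack(np.meshgrid(*[np.array([60, 140])] * 2,
                                    np.array([40, 80, 120, 160, 100]),
                                    indexing="ij"), -1).reshape(-1, 3)[:20]
        pts = grid + rng.uniform(-5, 5, grid.shape)
        vol = puncta_volume(pts, noise_sigma=10.0, peak=100.0, seed=1)
        det = detect_cells(vol, "spots")
        assert len(det) == 20
        d, _ = cKDTree(det.positions_um).query(pts)
        assert d.max() < 2.0

    def test_unresolvable_pair_merges_to_one(self):
        pts = [[100, 100, 98], [100, 100, 102]]  # 4 µm apart, radius 5 µm
        vol = puncta_volume(pts)
        det = detect_cells(vol, "spots", min_separation_um=5.0)
        assert len(det) == 1

    def test_detection_recall_precision_at_snr10(self):
        # counting-grade sampling: 3 µm voxels, densities well below the
        # packing limit of 5 µm-radius cells
        cfg = SimulationConfig(
            field_size_um=(500.0, 800.0, 800.0), voxel_size_um=(3.0, 3.0, 3.0),
            n_nodules=3, nodule_radius_range_um=(90.0, 150.0),
            tam_density_range_mm3=(10_000.0, 30_000.0), snr=10.0, seed=17,
        )
        volume, truth = generate_lung_volume(cfg)
        det = detect_cells(volume, "tam_np")
        true_pts = truth.cell_positions_um()
        d, _ = cKDTree(det.positions_um).query(true_pts)
        recall = (d < 5.0).mean()
        d2, _ = cKDTree(true_pts).query(det.positions_um)
        precision = (d2 < 5.0).mean()
        assert recall >= 0.95
        assert precision >= 0.95


class TestConcordance:
    def _map_from(self, labels, voxel=(5, 5, 5)):
        return NoduleLabelMap(np.asarray(labels, np.int32), voxel)

    def test_identity_gives_perfect_rank_correlation(self, segmented_small_lung):
        _, _, label_map, _ = segmented_small_lung
        res = segmentation_concordance(label_map, label_map)
        assert res.spearman_rho == pytest.approx(1.0, abs=1e-12)
        assert res.n_matched == label_map.n_nodules

    def test_reversed_volumes_give_minus_one(self):
        # 3 aligned nodules with volumes 1, 2, 3 voxels in map a and the
        # reversed sizes in map b (each pair overlapping in one voxel)
        a = np.zeros((1, 3, 6), np.int32)
        b = np.zeros((1, 3, 6), np.int32)
        a[0, 0, :1] = 1; b[0, 0, :3] = 1
        a[0, 1, :2] = 2; b[0, 1, :2] = 2
        a[0, 2, :3] = 3; b[0, 2, :1] = 3
        res = segmentation_concordance(self._map_from(a), self._map_from(b))
        assert res.n_matched == 3
        assert res.spearman_rho == pytest.approx(-1.0)

    def test_disjoint_maps_are_undefined(self):
        a = np.zeros((1, 2, 4), np.int32)
        b = np.zeros((1, 2, 4), np.int32)
        a[0, 0, 0] = 1
        b[0, 1, 3] = 1
        with pytest.raises(UndefinedStatisticError):
            segmentation_concordance(self._map_from(a), self._map_from(b))

    def test_grid_mismatch_rejected(self):
        a = self._map_from(np.ones((1, 2, 2)))
        b = self._map_from(np.ones((1, 2, 3)))
        with pytest.raises(ValueError, match="grid"):
            segmentation_concordance(a, b)
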