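import numpy as np
import pytest

from lungtam import (
    SimulationConfig,
    detect_cells,
    generate_lung_volume,
    segment_nodules,
)


@pytest.fixture(scope="session")
def small_lung():
    """A small 5-nodule lung field with ground truth (shared, read-only)."""
    cfg = SimulationConfig(
        field_size_um=(700.0, 1200.0, 1200.0),
        n_nodules=5,
        nodule_radius_range_um=(80.0, 180.0),
        seed=42,
    )
    return generate_lung_volume(cfg), cfg


@pytest.fixture(scope="session")
def segmented_small_lung(small_lung):
    (volume, truth), _ = small_lung
    label_map = segment_nodules(volume, "nuclear")
    detections = detect_cells(volume, "tam_np")
    return volume, truth, label_map, detections


@pytest.fixture(scope="session")
def clean_sphere():
    """One noiseless, blur-free sphere: exact voxelized-ellipsoid oracle."""
    cfg = SimulationConfig(
        field_size_um=(400.0, 400.0, 400.0),
        n_nodules=1,
        nodule_radius_range_um=(100.0, 100.0),
        axis_ratio_range=(1.0, 1.0),
        random_orientation=False,
        snr=None,
        psf_sigma_um=(0.0, 0.0, 0.0),
        tam_density_range_mm3=(0.0, 0.0),
        seed=7,
    )
    return generate_lung_volume(cfg)


def make_rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
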