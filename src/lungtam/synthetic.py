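"""Ground-truthed synthetic cleared-lung volumes.

The raw whole-lung datasets this analysis was designed for are not publicly
deposited, so every statistic in the pipeline is exercised against volumes
produced here, for which exact ground truth is known.  The generator emulates
the statistical structure the analysis relies on:

* lung parenchyma as a low, flat nuclear background;
* tumor nodules as ellipsoids of elevated nuclear density (the density
  contrast is what makes nodules segmentable from a nuclear stain);
* tumor-associated macrophages (TAM) as Gaussian puncta in a nanoparticle
  channel, placed uniformly, rim-biased, or core-biased inside each nodule
  at densities drawn log-uniformly from 8,000-60,000 cells mm^-3;
* a tumor-reporter (GFP-like) channel supported exactly on the nodules;
* separable Gaussian optical blur (larger sigma along z) and Gaussian
  shot-like noise whose variance grows with signal;
* optional per-nodule drug-carrier / drug channels whose levels track TAM
  density, for delivery-correlation analyses;
* a paired low-resolution "wide-field" rendering (max-intensity projection,
  blurred and downsampled) of the same field.

Determinism: one master seed; every nodule and every channel's noise draws
from its own `numpy` ``SeedSequence`` child stream keyed by
``(seed, purpose, index)``, so adding a nodule or a channel never perturbs
the others.  Identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import block_reduce

from .volume import ImageVolume

__all__ = [
    "SimulationConfig",
    "Nodule",
    "GroundTruth",
    "NodulePlacementError",
    "place_tam",
    "generate_lung_volume",
    "render_widefield",
    "simulate_single_nodule",
    "simulate_coloc_pair",
]

TAM_DENSITY_RANGE_MM3 = (8_000.0, 60_000.0)
SPATIAL_MODES = ("uniform", "rim", "core")


class NodulePlacementError(RuntimeError):
    """Raised when a nodule cannot be placed without overlap (field too crowded)."""


# ---------------------------------------------------------------------------
# configuration and ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of one synthetic lung field.  Axis order is (z, y, x), µm.

    ``snr`` is the nodule step over the background noise scale:
    ``(contrast - 1) * nuclear_background / sigma_noise(background)``.
    ``snr=None`` disables noise entirely.  TAM puncta peaks are set to
    ``snr * sigma_noise`` above the TAM-channel background so one knob
    controls the difficulty of both segmentation and spot detection.
    """

    field_size_um: tuple[float, float, float] = (800.0, 1600.0, 1600.0)
    voxel_size_um: tuple[float, float, float] = (5.0, 5.0, 5.0)
    n_nodules: int = 8
    nodule_radius_range_um: tuple[float, float] = (100.0, 250.0)
    nodule_contrast: float = 5.0
    axis_ratio_range: tuple[float, float] = (0.85, 1.18)
    random_orientation: bool = True
    tam_density_range_mm3: tuple[float, float] = TAM_DENSITY_RANGE_MM3
    tam_spatial_mode: str = "uniform"
    rim_bias_strength: float = 2.0
    tam_radius_um: float = 5.0
    nuclear_background: float = 100.0
    tam_background: float = 100.0
    snr: float | None = 10.0
    shot_fraction: float = 0.5
    psf_sigma_um: tuple[float, float, float] = (2.5, 1.5, 1.5)
    channels: tuple[str, ...] = ("nuclear", "tumor_reporter", "tam_np")
    include_drug_channels: bool = False
    drug_carrier_ratio: float = 0.8
    drug_noise_cv: float = 0.05
    placement_margin_um: float = 20.0
    max_placement_tries: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "field_size_um", "voxel_size_um", "nodule_radius_range_um",
            "axis_ratio_range", "tam_density_range_mm3", "psf_sigma_um",
        ):
            setattr(self, name, tuple(float(v) for v in getattr(self, name)))
        if any(v <= 0 for v in self.field_size_um + self.voxel_size_um):
            raise ValueError("field and voxel sizes must be strictly positive")
        lo, hi = self.nodule_radius_range_um
        if not (0 < lo <= hi):
            raise ValueError(f"bad nodule radius range {self.nodule_radius_range_um}")
        dlo, dhi = self.tam_density_range_mm3
        if not (0 <= dlo <= dhi):
            raise ValueError(f"bad TAM density range {self.tam_density_range_mm3}")
        if self.nodule_contrast <= 1:
            raise ValueError("nodule_contrast must exceed 1 (nodules are denser)")
        if self.tam_spatial_mode not in SPATIAL_MODES:
            raise ValueError(f"tam_spatial_mode must be one of {SPATIAL_MODES}")
        if self.rim_bias_strength < 0:
            raise ValueError("rim_bias_strength must be >= 0")
        self.channels = tuple(self.channels)
        known = {"nuclear", "tumor_reporter", "tam_np"}
        if not set(self.channels) <= known or not self.channels:
            raise ValueError(f"channels must be a nonempty subset of {known}")
        if self.n_nodules < 0:
            raise ValueError("n_nodules must be >= 0")
        # every nodule must be able to fit inside the field with its margin
        worst = 2 * (hi * self.axis_ratio_range[1] + self.placement_margin_um)
        if self.n_nodules > 0 and worst > min(self.field_size_um):
            raise ValueError(
                "largest allowed nodule does not fit inside the field "
                f"({worst:.0f} µm needed, {min(self.field_size_um):.0f} µm available)"
            )

    # noise model: variance = read^2 + gain * signal (shot-like)
    def noise_params(self) -> tuple[float, float]:
        if self.snr is None or not math.isfinite(self.snr):
            return (0.0, 0.0)
        sigma_bg = (self.nodule_contrast - 1) * self.nuclear_background / self.snr
        gain = self.shot_fraction * sigma_bg**2 / self.nuclear_background
        read2 = max(sigma_bg**2 - gain * self.nuclear_background, 0.0)
        return (read2, gain)

    def noise_sigma(self, signal: float) -> float:
        read2, gain = self.noise_params()
        return math.sqrt(read2 + gain * signal)


@dataclass
class Nodule:
    """One ellipsoidal nodule: geometry plus realized TAM ground truth."""

    id: int
    center_um: np.ndarray  # (3,) z,y,x
    semi_axes_um: np.ndarray  # (3,) z,y,x, in the ellipsoid's local frame
    rotation: np.ndarray  # (3,3) local -> world
    spatial_mode: str = "uniform"
    tam_count: int = 0
    tam_density_mm3: float = 0.0

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes_um
        return 4.0 / 3.0 * math.pi * a * b * c / 1e9

    def world_halfwidths_um(self) -> np.ndarray:
        """Half-extent of the rotated ellipsoid along each world axis."""
        return np.sqrt(((self.rotation * self.semi_axes_um[None, :]) ** 2).sum(axis=1))

    def local_coords(self, points_um: np.ndarray) -> np.ndarray:
        """Points mapped to the unit-ball frame (|u| <= 1 inside)."""
        d = np.atleast_2d(points_um) - self.center_um
        return (d @ self.rotation) / self.semi_axes_um

    def contains(self, points_um: np.ndarray) -> np.ndarray:
        u = self.local_coords(points_um)
        return (u**2).sum(axis=1) <= 1.0

    def rasterize(self, shape: Sequence[int], voxel_size: Sequence[float]) -> tuple:
        """Boolean in-ellipsoid mask restricted to a bounding box.

        Returns ``(slices, mask)`` where ``slices`` index the full array.
        """
        voxel = np.asarray(voxel_size, float)
        hw = self.world_halfwidths_um() + voxel  # one voxel of slack
        lo = np.maximum(np.floor((self.center_um - hw) / voxel - 0.5), 0).astype(int)
        hi = np.minimum(
            np.ceil((self.center_um + hw) / voxel - 0.5).astype(int) + 1,
            np.asarray(shape),
        )
        slices = tuple(slice(a, b) for a, b in zip(lo, hi))
        grids = np.meshgrid(
            *[(np.arange(a, b) + 0.5) * v for a, b, v in zip(lo, hi, voxel)],
            indexing="ij",
        )
        pts = np.stack([g.ravel() for g in grids], axis=1)
        mask = self.contains(pts).reshape([b - a for a, b in zip(lo, hi)])
        return slices, mask


@dataclass
class GroundTruth:
    """Everything the generator knows: nodules, cells, channel parameters."""

    nodules: list[Nodule]
    cells: pd.DataFrame  # cell_id, nodule_id, x_um, y_um, z_um, channels
    channel_params: dict = field(default_factory=dict)

    def nodules_frame(self) -> pd.DataFrame:
        rows = []
        for n in self.nodules:
            cz, cy, cx = n.center_um
            rz, ry, rx = n.semi_axes_um
            rows.append(
                dict(
                    id=n.id, cx_um=cx, cy_um=cy, cz_um=cz,
                    rx_um=rx, ry_um=ry, rz_um=rz,
                    volume_mm3=n.volume_mm3, tam_count=n.tam_count,
                    tam_density_mm3=n.tam_density_mm3, spatial_mode=n.spatial_mode,
                )
            )
        cols = ["id", "cx_um", "cy_um", "cz_um", "rx_um", "ry_um", "rz_um",
                "volume_mm3", "tam_count", "tam_density_mm3", "spatial_mode"]
        return pd.DataFrame(rows, columns=cols)

    def cell_positions_um(self, nodule_id: int | None = None) -> np.ndarray:
        df = self.cells
        if nodule_id is not None:
            df = df[df.nodule_id == nodule_id]
        return df[["z_um", "y_um", "x_um"]].to_numpy(float)


# ---------------------------------------------------------------------------
# RNG streams
# ---------------------------------------------------------------------------


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


_PLACEMENT, _NODULE, _NOISE, _AUX = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# TAM placement inside an ellipsoid
# ---------------------------------------------------------------------------


def _sample_radii(n: int, mode: str, bias: float, rng: np.random.Generator) -> np.ndarray:
    """Normalized radii in [0, 1] for n points.

    The radial pdf is proportional to r^2 * w(r) with weight w = 1 (uniform),
    r^bias (rim) or (1-r)^bias (core); uniform and rim invert analytically,
    core uses rejection against the uniform-in-ball proposal.
    """
    if mode == "uniform":
        return rng.random(n) ** (1.0 / 3.0)
    if mode == "rim":
        return rng.random(n) ** (1.0 / (3.0 + bias))
    if mode == "core":
        out = np.empty(0)
        while out.size < n:
            batch = max(4 * (n - out.size), 64)
            r = rng.random(batch) ** (1.0 / 3.0)
            keep = rng.random(batch) <= (1.0 - r) ** bias
            out = np.concatenate([out, r[keep]])
        return out[:n]
    raise ValueError(f"unknown spatial mode {mode!r}")


def place_tam(
    nodule: Nodule,
    density_mm3: float,
    mode: str = "uniform",
    bias: float = 2.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample TAM positions (µm, z/y/x) inside one nodule.

    The count is Poisson with mean ``density * volume``; radial placement
    follows ``mode`` (uniform in the ellipsoid, rim-biased ~ r^bias, or
    core-biased ~ (1-r)^bias).  All returned points lie inside the ellipsoid.
    """
    if density_mm3 < 0:
        raise ValueError(f"TAM density must be >= 0, got {density_mm3}")
    if mode not in SPATIAL_MODES:
        raise ValueError(f"mode must be one of {SPATIAL_MODES}")
    rng = np.random.default_rng() if rng is None else rng
    n = int(rng.poisson(density_mm3 * nodule.volume_mm3))
    if n == 0:
        return np.empty((0, 3))
    r = _sample_radii(n, mode, bias, rng)
    d = rng.normal(size=(n, 3))
    d /= np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-12)
    local = d * r[:, None] * nodule.semi_axes_um
    return nodule.center_um + local @ nodule.rotation.T


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _deposit_points(shape, voxel, points_um, values) -> np.ndarray:
    """Trilinearly deposit point masses onto the voxel grid."""
    img = np.zeros(shape, dtype=np.float64)
    if len(points_um) == 0:
        return img
    f = np.asarray(points_um) / np.asarray(voxel) - 0.5
    i0 = np.floor(f).astype(int)
    w1 = f - i0
    w0 = 1.0 - w1
    vals = np.broadcast_to(np.asarray(values, float), (len(f),))
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                idx = i0 + np.array([dz, dy, dx])
                w = (
                    (w1[:, 0] if dz else w0[:, 0])
                    * (w1[:, 1] if dy else w0[:, 1])
                    * (w1[:, 2] if dx else w0[:, 2])
                )
                ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
                np.add.at(img, tuple(idx[ok].T), vals[ok] * w[ok])
    return img


def _delta_peak(sigma_vox: np.ndarray) -> float:
    """Peak response of a unit point mass after Gaussian blur on this grid."""
    peak = 1.0
    for s in sigma_vox:
        if s <= 0:
            continue
        half = int(math.ceil(4 * s)) + 1
        line = np.zeros(2 * half + 1)
        line[half] = 1.0
        peak *= ndimage.gaussian_filter1d(line, s).max()
    return peak


def render_puncta(
    shape, voxel, points_um, peak, punctum_sigma_um, psf_sigma_um
) -> np.ndarray:
    """Render point sources as Gaussian puncta convolved with the PSF.

    ``peak`` is the target post-blur amplitude of an isolated on-grid
    punctum; overlapping puncta add.
    """
    sigma_um = np.sqrt(
        np.asarray(punctum_sigma_um, float) ** 2 + np.asarray(psf_sigma_um, float) ** 2
    )
    sigma_vox = sigma_um / np.asarray(voxel, float)
    norm = _delta_peak(sigma_vox)
    img = _deposit_points(shape, voxel, points_um, peak / norm)
    return ndimage.gaussian_filter(img, sigma_vox)


# ---------------------------------------------------------------------------
# full field generation
# ---------------------------------------------------------------------------


def _place_nodules(config: SimulationConfig) -> list[Nodule]:
    rng = _stream(config.seed, _PLACEMENT)
    field = np.asarray(config.field_size_um)
    geoms = []
    for _ in range(config.n_nodules):
        radius = rng.uniform(*config.nodule_radius_range_um)
        semi = radius * rng.uniform(*config.axis_ratio_range, size=3)
        rot = _random_rotation(rng) if config.random_orientation else np.eye(3)
        geoms.append((semi, rot))
    # place the big ones first — greedy packing fails far less often
    geoms.sort(key=lambda g: -float(g[0].max()))
    nodules: list[Nodule] = []
    for i, (semi, rot) in enumerate(geoms):
        placed = False
        for _ in range(config.max_placement_tries):
            probe = Nodule(i + 1, np.zeros(3), semi, rot)
            hw = probe.world_halfwidths_um() + config.placement_margin_um
            if np.any(field - 2 * hw <= 0):
                break
            center = rng.uniform(hw, field - hw)
            reach = semi.max() + config.placement_margin_um
            ok = all(
                np.linalg.norm(center - n.center_um)
                > reach + n.semi_axes_um.max() + config.placement_margin_um
                for n in nodules
            )
            if ok:
                nodules.append(
                    Nodule(i + 1, center, semi, rot, config.tam_spatial_mode)
                )
                placed = True
                break
        if not placed:
            raise NodulePlacementError(
                f"could not place nodule {i + 1} of {config.n_nodules} after "
                f"{config.max_placement_tries} tries; field too crowded"
            )
    return nodules


def _sample_density(config: SimulationConfig, rng: np.random.Generator) -> float:
    lo, hi = config.tam_density_range_mm3
    if lo == hi:
        return float(lo)
    if lo <= 0:
        return float(rng.uniform(lo, hi))
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_lung_volume(config: SimulationConfig) -> tuple[ImageVolume, GroundTruth]:
    """Generate one multi-channel cleared-lung field with ground truth.

    Channels: ``nuclear`` (background plus contrast-elevated nodules),
    ``tumor_reporter`` (supported exactly on the nodules before blur),
    ``tam_np`` (TAM puncta over a dim background), and optionally
    ``carrier``/``drug`` whose per-nodule levels track TAM density.
    """
    shape = tuple(
        int(round(f / v)) for f, v in zip(config.field_size_um, config.voxel_size_um)
    )
    voxel = config.voxel_size_um
    nodules = _place_nodules(config)

    bg = config.nuclear_background
    step = (config.nodule_contrast - 1) * bg
    nodule_struct = np.zeros(shape, dtype=np.float64)

    cells_rows = []
    all_points: list[np.ndarray] = []
    cell_id = 0
    for n in nodules:
        rng_n = _stream(config.seed, _NODULE, n.id)
        density = _sample_density(config, rng_n)
        pts = place_tam(
            n, density, config.tam_spatial_mode, config.rim_bias_strength, rng_n
        )
        n.tam_count = len(pts)
        n.tam_density_mm3 = len(pts) / n.volume_mm3
        all_points.append(pts)
        for p in pts:
            cells_rows.append(
                dict(cell_id=cell_id, nodule_id=n.id,
                     x_um=p[2], y_um=p[1], z_um=p[0], channels="tam_np")
            )
            cell_id += 1
        sl, mask = n.rasterize(shape, voxel)
        nodule_struct[sl][mask] = 1.0

    points = (
        np.concatenate(all_points, axis=0) if all_points else np.empty((0, 3))
    )
    cells = pd.DataFrame(
        cells_rows, columns=["cell_id", "nodule_id", "x_um", "y_um", "z_um", "channels"]
    )

    psf = np.asarray(config.psf_sigma_um, float)
    psf_vox = psf / np.asarray(voxel)

    def blur(a: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(a, psf_vox) if psf_vox.max() > 0 else a

    read2, gain = config.noise_params()
    tam_peak = (
        config.snr * config.noise_sigma(config.tam_background)
        if read2 + gain > 0
        else 5.0 * config.tam_background
    )

    channels: dict[str, np.ndarray] = {}
    channel_params: dict = {}
    if "nuclear" in config.channels:
        channels["nuclear"] = bg + blur(step * nodule_struct)
        channel_params["nuclear"] = {
            "background": bg, "nodule_level": bg * config.nodule_contrast,
        }
    if "tumor_reporter" in config.channels:
        channels["tumor_reporter"] = blur(step * nodule_struct)
        channel_params["tumor_reporter"] = {"background": 0.0, "nodule_level": step}
    if "tam_np" in config.channels:
        channels["tam_np"] = config.tam_background + render_puncta(
            shape, voxel, points, tam_peak, config.tam_radius_um / 2.0, psf
        )
        channel_params["tam_np"] = {
            "background": config.tam_background, "punctum_peak": tam_peak,
        }

    if config.include_drug_channels:
        rng_d = _stream(config.seed, _AUX, 0)
        carrier = np.zeros(shape)
        drug = np.zeros(shape)
        levels = []
        for n in nodules:
            base = step * n.tam_density_mm3 / 17_000.0
            c_lvl = base * max(1.0 + config.drug_noise_cv * rng_d.normal(), 0.05)
            d_lvl = (
                config.drug_carrier_ratio
                * c_lvl
                * max(1.0 + config.drug_noise_cv * rng_d.normal(), 0.05)
            )
            sl, mask = n.rasterize(shape, voxel)
            carrier[sl][mask] = c_lvl
            drug[sl][mask] = d_lvl
            levels.append(dict(nodule_id=n.id, carrier_level=c_lvl, drug_level=d_lvl))
        channels["carrier"] = blur(carrier)
        channels["drug"] = blur(drug)
        channel_params["carrier"] = {"per_nodule": levels}
        channel_params["drug"] = {"ratio": config.drug_carrier_ratio}

    if read2 + gain > 0:
        # fixed stream index per channel name: dropping a channel never
        # perturbs the noise of the others
        stream_ids = {"nuclear": 0, "tumor_reporter": 1, "tam_np": 2,
                      "carrier": 3, "drug": 4}
        for name, arr in channels.items():
            rng_c = _stream(config.seed, _NOISE, stream_ids[name])
            sigma = np.sqrt(read2 + gain * arr)
            channels[name] = np.clip(arr + rng_c.normal(size=shape) * sigma, 0, None)

    channels = {k: v.astype(np.float32) for k, v in channels.items()}
    vol = ImageVolume(
        channels, voxel, meta={"seed": config.seed, "generator": "lungtam.synthetic"}
    )
    return vol, GroundTruth(nodules, cells, channel_params)


# ---------------------------------------------------------------------------
# wide-field rendering
# ---------------------------------------------------------------------------


def render_widefield(
    volume: ImageVolume, downsample_factor: int = 4, blur_sigma_um: float = 10.0
) -> ImageVolume:
    """Low-magnification overview: per channel, max-intensity projection along
    z, Gaussian blur, then block-mean downsampling.  Pixel sizes in the
    returned 2D image are scaled by ``downsample_factor``."""
    if volume.ndim != 3:
        raise ValueError("render_widefield expects a 3D volume")
    factor = int(downsample_factor)
    if factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    vy, vx = volume.voxel_size[1], volume.voxel_size[2]
    out: dict[str, np.ndarray] = {}
    for name, arr in volume.channels.items():
        mip = arr.max(axis=0).astype(np.float64)
        if blur_sigma_um > 0:
            mip = ndimage.gaussian_filter(mip, (blur_sigma_um / vy, blur_sigma_um / vx))
        if factor > 1:
            ny = (mip.shape[0] // factor) * factor
            nx = (mip.shape[1] // factor) * factor
            mip = block_reduce(mip[:ny, :nx], (factor, factor), np.mean)
        out[name] = mip.astype(np.float32)
    meta = dict(volume.meta)
    meta.update(projection="max", downsample_factor=factor, blur_sigma_um=blur_sigma_um)
    return ImageVolume(out, (vy * factor, vx * factor), meta=meta)


# ---------------------------------------------------------------------------
# convenience generators for focused experiments
# ---------------------------------------------------------------------------


def simulate_single_nodule(
    radius_um: float = 120.0,
    density_mm3: float = 30_000.0,
    mode: str = "uniform",
    bias: float = 2.0,
    snr: float | None = 10.0,
    voxel_um: float = 4.0,
    margin_um: float = 60.0,
    seed: int = 0,
    **overrides,
) -> tuple[ImageVolume, GroundTruth]:
    """One nodule in a snug field — the workhorse for core/rim profiling."""
    side = 2 * (radius_um * 1.2 + margin_um)
    cfg = SimulationConfig(
        field_size_um=(side, side, side),
        voxel_size_um=(voxel_um, voxel_um, voxel_um),
        n_nodules=1,
        nodule_radius_range_um=(radius_um, radius_um),
        tam_density_range_mm3=(density_mm3, density_mm3),
        tam_spatial_mode=mode,
        rim_bias_strength=bias,
        snr=snr,
        placement_margin_um=margin_um / 2,
        seed=seed,
        **overrides,
    )
    return generate_lung_volume(cfg)


def simulate_coloc_pair(
    n_cells: int = 250,
    subset_fraction: float = 0.8,
    extra_fraction: float = 0.0,
    radius_um: float = 200.0,
    voxel_um: float = 2.5,
    snr: float | None = 10.0,
    cell_radius_um: float = 5.0,
    seed: int = 0,
) -> tuple[ImageVolume, np.ndarray, np.ndarray]:
    """Two punctate channels with known object-level overlap.

    Channel ``cells_a`` holds ``n_cells`` puncta uniformly placed in a
    sphere; channel ``cells_b`` holds an exact ``subset_fraction`` of the
    same positions plus ``extra_fraction * n_cells`` independent extras.
    Returns the rendered two-channel volume and the true point sets.
    """
    if not 0 <= subset_fraction <= 1:
        raise ValueError("subset_fraction must lie in [0, 1]")
    rng = _stream(seed, _AUX, 1)
    side = 2 * (radius_um + 10 * cell_radius_um)
    shape = (int(side / voxel_um),) * 3
    voxel = (voxel_um,) * 3
    center = np.full(3, side / 2)

    r = rng.random(n_cells) ** (1 / 3)
    d = rng.normal(size=(n_cells, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    pts_a = center + d * r[:, None] * radius_um

    n_sub = int(round(subset_fraction * n_cells))
    order = rng.permutation(n_cells)
    pts_b = pts_a[order[:n_sub]]
    n_extra = int(round(extra_fraction * n_cells))
    if n_extra:
        re_ = rng.random(n_extra) ** (1 / 3)
        de = rng.normal(size=(n_extra, 3))
        de /= np.linalg.norm(de, axis=1, keepdims=True)
        pts_b = np.vstack([pts_b, center + de * re_[:, None] * radius_um])

    noise_sigma = 1.0
    background = 10.0 * noise_sigma  # keeps the noise floor clear of zero
    peak = (snr if snr is not None and math.isfinite(snr) else 10.0) * noise_sigma
    psf = (1.5, 1.0, 1.0)
    channels = {}
    for name, pts in (("cells_a", pts_a), ("cells_b", pts_b)):
        channels[name] = background + render_puncta(
            shape, voxel, pts, peak, cell_radius_um / 2.0, psf
        )
    if snr is not None and math.isfinite(snr):
        for idx, name in enumerate(sorted(channels)):
            rng_c = _stream(seed, _NOISE, 10 + idx)
            channels[name] = np.clip(
                channels[name] + rng_c.normal(size=shape) * noise_sigma, 0, None
            )
    channels = {k: v.astype(np.float32) for k, v in channels.items()}
    vol = ImageVolume(channels, voxel, meta={"seed": seed, "nodule_radius_um": radius_um})
    return vol, pts_a, pts_b
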