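"""Multi-channel image volumes with physical (micrometre) metadata.

All 3D arrays are indexed ``(z, y, x)`` and 2D arrays ``(y, x)``.  Physical
coordinates are micrometres; the centre of voxel ``i`` along an axis with
voxel size ``v`` sits at ``(i + 0.5) * v`` (half-open voxel convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = ["ImageVolume", "UndefinedStatisticError"]


class UndefinedStatisticError(ValueError):
    """A requested statistic is mathematically undefined for this input
    (e.g. a correlation of a constant signal, or zero matched pairs)."""


@dataclass
class ImageVolume:
    """A multi-channel intensity volume (3D) or image (2D) with voxel sizes.

    Parameters
    ----------
    channels
        Mapping of channel name to intensity array.  All channels must share
        one shape and one dimensionality (3 for stacks, 2 for wide-field
        renderings).  Intensities must be finite and non-negative.
    voxel_size
        Micrometres per voxel along each axis, same length as the array
        dimensionality, ordered ``(z, y, x)`` (or ``(y, x)`` for 2D).
    meta
        Free-form provenance (seed, config hash, ...), carried through I/O.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageVolume needs at least one channel")
        shapes = {arr.shape for arr in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != self.ndim:
            raise ValueError(
                f"voxel_size has {len(self.voxel_size)} entries for a "
                f"{self.ndim}D volume"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be strictly positive: {self.voxel_size}")
        for name, arr in self.channels.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")

    # -- basic geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def ndim(self) -> int:
        return next(iter(self.channels.values())).ndim

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def extent_um(self) -> tuple[float, ...]:
        """Physical field size in µm per axis."""
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size))

    @property
    def voxel_volume_mm3(self) -> float:
        if self.ndim != 3:
            raise ValueError("voxel volume only defined for 3D volumes")
        return float(np.prod(self.voxel_size)) / 1e9

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not found; available: {self.channel_names}"
            ) from None

    # -- coordinate transforms ---------------------------------------------

    def index_to_um(self, idx: np.ndarray) -> np.ndarray:
        """Voxel indices (possibly fractional) to physical µm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return (idx + 0.5) * np.asarray(self.voxel_size)

    def um_to_index(self, pos_um: np.ndarray) -> np.ndarray:
        """Physical µm coordinates to fractional voxel indices."""
        pos_um = np.asarray(pos_um, dtype=float)
        return pos_um / np.asarray(self.voxel_size) - 0.5

    def contains_um(self, pos_um: np.ndarray) -> np.ndarray:
        """Boolean mask: which points lie inside the physical extent."""
        pos_um = np.atleast_2d(np.asarray(pos_um, dtype=float))
        ext = np.asarray(self.extent_um)
        return np.all((pos_um >= 0) & (pos_um <= ext), axis=1)


def as_points_um(points: "np.ndarray | Iterable") -> np.ndarray:
    """Coerce to an (N, D) float array of physical coordinates."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 3)
    if pts.ndim == 1:
        pts = pts[None, :]
    return pts
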