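"""Reading and writing volumes, label maps and tables.

Volumes travel as multi-page TIFF (one file per channel, z as pages) with a
JSON metadata sidecar carrying the voxel sizes in µm, or as a single
OME-TIFF whose PhysicalSize fields carry the same information.  Voxel size
is mandatory on read — a file without physical calibration is rejected
rather than silently assumed isotropic at 1 µm.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segmentation import NoduleLabelMap, SegmentationParams
from .volume import ImageVolume

__all__ = [
    "MissingVoxelSizeError",
    "write_volume",
    "read_volume",
    "write_label_map",
    "read_label_map",
    "write_table",
]

SIDECAR_NAME = "volume_meta.json"
FLOAT_FORMAT = "%.8g"  # fixed precision so outputs are byte-stable


class MissingVoxelSizeError(ValueError):
    """The file carries no voxel-size (PhysicalSize) metadata."""


def write_volume(volume: ImageVolume, path: str | Path, ome: bool = False) -> Path:
    """Write a 3D volume to ``path``.

    ``ome=False`` (default): ``path`` is a directory receiving one
    multi-page TIFF per channel plus a ``volume_meta.json`` sidecar.
    ``ome=True``: ``path`` is a single ``.ome.tif`` with CZYX axes and
    PhysicalSizeX/Y/Z metadata.
    """
    path = Path(path)
    if volume.ndim != 3:
        raise ValueError("write_volume expects a 3D volume")
    if ome:
        path.parent.mkdir(parents=True, exist_ok=True)
        stack = np.stack([volume.channels[c] for c in volume.channel_names])
        vz, vy, vx = volume.voxel_size
        tifffile.imwrite(
            path,
            stack,
            ome=True,
            metadata={
                "axes": "CZYX",
                "PhysicalSizeZ": vz, "PhysicalSizeZUnit": "µm",
                "PhysicalSizeY": vy, "PhysicalSizeYUnit": "µm",
                "PhysicalSizeX": vx, "PhysicalSizeXUnit": "µm",
                "Channel": {"Name": volume.channel_names},
            },
        )
        return path
    path.mkdir(parents=True, exist_ok=True)
    for name, arr in volume.channels.items():
        tifffile.imwrite(path / f"{name}.tif", arr, photometric="minisblack")
    meta = {
        "voxel_size_um": list(volume.voxel_size),
        "channels": volume.channel_names,
        **{k: v for k, v in volume.meta.items() if _jsonable(v)},
    }
    (path / SIDECAR_NAME).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _read_ome(path: Path) -> ImageVolume:
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        ome_xml = tif.ome_metadata
    if ome_xml is None:
        raise MissingVoxelSizeError(f"{path} has no OME metadata")
    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is None:
        raise MissingVoxelSizeError(f"{path}: OME metadata lacks a Pixels element")
    voxel = []
    for field in ("PhysicalSizeZ", "PhysicalSizeY", "PhysicalSizeX"):
        if field not in pixels.attrib:
            raise MissingVoxelSizeError(f"{path}: OME metadata lacks {field}")
        voxel.append(float(pixels.attrib[field]))
    names = [
        ch.attrib.get("Name", f"channel_{i}")
        for i, ch in enumerate(root.findall(".//ome:Channel", ns))
    ]
    if arr.ndim == 3:  # single channel
        arr = arr[None]
    if not names or len(names) != arr.shape[0]:
        names = [f"channel_{i}" for i in range(arr.shape[0])]
    channels = {n: arr[i] for i, n in enumerate(names)}
    return ImageVolume(channels, tuple(voxel), meta={"source": str(path)})


def read_volume(path: str | Path) -> ImageVolume:
    """Read a volume written by :func:`write_volume` (directory or OME-TIFF)."""
    path = Path(path)
    if path.is_file():
        return _read_ome(path)
    sidecar = path / SIDECAR_NAME
    if not sidecar.exists():
        raise MissingVoxelSizeError(
            f"{path} has no {SIDECAR_NAME} sidecar; voxel_size_um is required "
            "(physical calibration is never assumed)"
        )
    meta = json.loads(sidecar.read_text())
    if "voxel_size_um" not in meta:
        raise MissingVoxelSizeError(f"{sidecar} lacks the field 'voxel_size_um'")
    channels = {
        name: tifffile.imread(path / f"{name}.tif") for name in meta["channels"]
    }
    voxel = tuple(meta["voxel_size_um"])
    extra = {k: v for k, v in meta.items() if k not in ("voxel_size_um", "channels")}
    return ImageVolume(channels, voxel, meta=extra)


def write_label_map(label_map: NoduleLabelMap, path: str | Path) -> Path:
    """Persist a label map as integer TIFF plus a legend CSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path / "labels.tif", label_map.labels.astype(np.int32),
                     photometric="minisblack")
    legend = pd.DataFrame(
        dict(
            nodule_id=label_map.nodule_ids(),
            volume_mm3=label_map.volumes_mm3().loc[label_map.nodule_ids()].to_numpy(),
            border=[label_map.is_border(int(i)) for i in label_map.nodule_ids()],
        )
    )
    legend.to_csv(path / "labels_legend.csv", index=False, float_format=FLOAT_FORMAT)
    meta = dict(
        voxel_size_um=list(label_map.voxel_size),
        channel=label_map.channel,
        params=vars(label_map.params) if label_map.params else None,
        border_labels=sorted(label_map.border_labels),
    )
    (path / "labels_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_label_map(path: str | Path) -> NoduleLabelMap:
    path = Path(path)
    meta = json.loads((path / "labels_meta.json").read_text())
    params = SegmentationParams(**meta["params"]) if meta.get("params") else None
    return NoduleLabelMap(
        tifffile.imread(path / "labels.tif"),
        tuple(meta["voxel_size_um"]),
        meta.get("channel", ""),
        params,
        frozenset(meta.get("border_labels", [])),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """CSV with fixed column order and fixed float precision (byte-stable)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path
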