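"""Per-nodule quantification and the wide-field ↔ cell-count calibration.

Units follow the imaging literature: coordinates in µm, nodule volumes in
mm³ (1 mm³ = 1e9 µm³), TAM densities in cells mm⁻³, wide-field "integrated
fluorescence density" as background-subtracted summed intensity per µm² of
projected nodule footprint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import block_reduce

from .segmentation import CellDetections, NoduleLabelMap
from .volume import ImageVolume, UndefinedStatisticError

__all__ = [
    "BurdenResult",
    "CalibrationModel",
    "CorrelationResult",
    "compute_tumor_burden",
    "compute_tam_density",
    "widefield_integrated_density",
    "nodule_footprints",
    "fit_calibration",
    "infer_density_from_widefield",
    "nodule_signal_correlations",
]


@dataclass
class BurdenResult:
    """Total tumor burden of one lung plus the per-nodule breakdown."""

    per_nodule: pd.DataFrame  # nodule_id, n_voxels, volume_mm3
    total_mm3: float
    n_nodules: int


def compute_tumor_burden(label_map: NoduleLabelMap) -> BurdenResult:
    """Per-nodule volumes (voxel count × voxel volume) and their sum."""
    counts = np.bincount(label_map.labels.ravel())
    ids = np.arange(1, len(counts))
    present = counts[1:] > 0
    df = pd.DataFrame(
        dict(
            nodule_id=ids[present],
            n_voxels=counts[1:][present],
            volume_mm3=counts[1:][present] * label_map.voxel_volume_mm3,
        )
    )
    return BurdenResult(df, float(df.volume_mm3.sum()), len(df))


def compute_tam_density(
    label_map: NoduleLabelMap,
    detections: CellDetections,
    volume: ImageVolume | None = None,
) -> pd.DataFrame:
    """Assign detections to nodules and compute per-nodule TAM densities.

    Each detection is assigned to the nodule label of its containing voxel;
    detections falling on background are tallied as peritumoral and excluded
    from every density (strict containment).  Densities are counts divided
    by the segmented nodule volume.  If ``volume`` is given, per-channel
    mean and integrated intensities over each nodule are appended.

    Returns a nodule table with one row per segmented nodule plus the count
    of peritumoral detections in ``df.attrs['n_peritumoral']``.
    """
    burden = compute_tumor_burden(label_map)
    labels = label_map.labels
    voxel = np.asarray(label_map.voxel_size)
    pts = np.atleast_2d(detections.positions_um) if len(detections) else np.empty((0, 3))

    idx = np.floor(pts / voxel).astype(int) if len(pts) else np.empty((0, 3), int)
    if len(pts):
        bad = np.any((idx < 0) | (idx >= np.asarray(labels.shape)), axis=1)
        if bad.any():
            p = pts[np.flatnonzero(bad)[0]]
            raise ValueError(
                f"detection at (z,y,x)=({p[0]:.1f}, {p[1]:.1f}, {p[2]:.1f}) µm "
                "lies outside the volume extent"
            )
        owner = labels[tuple(idx.T)]
    else:
        owner = np.empty(0, int)

    n_peri = int((owner == 0).sum())
    tam_counts = np.bincount(owner[owner > 0], minlength=int(labels.max()) + 1)

    # centroids in µm (z, y, x), intensity-free (mask-based)
    rows = []
    for _, r in burden.per_nodule.iterrows():
        nid = int(r.nodule_id)
        where = np.argwhere(labels == nid)
        centroid = (where.mean(axis=0) + 0.5) * voxel
        count = int(tam_counts[nid]) if nid < len(tam_counts) else 0
        rows.append(
            dict(
                nodule_id=nid,
                volume_mm3=float(r.volume_mm3),
                cz_um=centroid[0], cy_um=centroid[1], cx_um=centroid[2],
                tam_count=count,
                tam_density_mm3=count / float(r.volume_mm3),
                border=bool(label_map.is_border(nid)),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["nodule_id", "volume_mm3", "cz_um", "cy_um", "cx_um",
                 "tam_count", "tam_density_mm3", "border"],
    )

    if volume is not None:
        if volume.shape != labels.shape:
            raise ValueError("intensity volume and label map must share one grid")
        for name, arr in volume.channels.items():
            sums = np.asarray(
                [arr[labels == int(n)].sum() for n in table.nodule_id], float
            )
            nvox = burden.per_nodule.set_index("nodule_id").n_voxels
            nvox = nvox.loc[table.nodule_id].to_numpy(float)
            table[f"{name}_mean"] = sums / nvox
            table[f"{name}_integrated"] = sums
    table.attrs["n_peritumoral"] = n_peri
    return table


# ---------------------------------------------------------------------------
# wide-field integrated density and calibration
# ---------------------------------------------------------------------------


def nodule_footprints(label_map: NoduleLabelMap, downsample_factor: int = 1) -> np.ndarray:
    """Project the 3D label map to the 2D wide-field grid (max along z,
    then block-max downsampling), preserving labels."""
    proj = label_map.labels.max(axis=0)
    f = int(downsample_factor)
    if f > 1:
        ny, nx = (proj.shape[0] // f) * f, (proj.shape[1] // f) * f
        proj = block_reduce(proj[:ny, :nx], (f, f), np.max)
    return proj


def widefield_integrated_density(
    widefield: ImageVolume, footprints: np.ndarray, channel: str = "tam_np"
) -> pd.DataFrame:
    """Background-subtracted summed intensity per unit projected area (µm²).

    Background is the median pixel value outside all footprints; negative
    background-subtracted pixels are clipped to zero before summing.
    """
    if widefield.ndim != 2:
        raise ValueError("widefield_integrated_density expects a 2D image")
    img = widefield.channel(channel).astype(np.float64)
    if footprints.shape != img.shape:
        raise ValueError(
            f"footprint grid {footprints.shape} does not match image {img.shape}"
        )
    outside = footprints == 0
    background = float(np.median(img[outside])) if outside.any() else 0.0
    pixel_area = float(np.prod(widefield.voxel_size))
    rows = []
    for nid in np.unique(footprints[footprints > 0]):
        sel = footprints == nid
        if not sel.any():
            raise ValueError(f"footprint of nodule {nid} is empty")
        excess = np.clip(img[sel] - background, 0, None)
        rows.append(
            dict(
                nodule_id=int(nid),
                footprint_area_um2=float(sel.sum() * pixel_area),
                integrated_density=float(excess.sum() / (sel.sum() * pixel_area)),
            )
        )
    df = pd.DataFrame(rows, columns=["nodule_id", "footprint_area_um2",
                                     "integrated_density"])
    df.attrs["background"] = background
    return df


@dataclass
class CalibrationModel:
    """Linear map from wide-field fluorescence density to cell count.

    ``mode='through_origin'`` (default) is a pure conversion factor;
    ``'free_intercept'`` is ordinary least squares.
    """

    slope: float
    intercept: float
    pearson_r: float
    n_pairs: int
    mode: str = "through_origin"

    def predict(self, density: np.ndarray) -> np.ndarray:
        if not np.isfinite(self.slope):
            raise ValueError("calibration model is not fitted")
        return self.slope * np.asarray(density, float) + self.intercept


def fit_calibration(
    widefield_density: np.ndarray,
    cell_counts: np.ndarray,
    mode: str = "through_origin",
) -> CalibrationModel:
    """Fit the wide-field density → cell count conversion and report Pearson r."""
    x = np.asarray(widefield_density, float)
    y = np.asarray(cell_counts, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("widefield_density and cell_counts must be 1D and paired")
    if len(x) < 3:
        raise ValueError(f"need >= 3 pairs to calibrate, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("calibration pairs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance in calibration pairs")
    r = float(stats.pearsonr(x, y).statistic)
    if mode == "through_origin":
        slope = float(x @ y / (x @ x))
        intercept = 0.0
    elif mode == "free_intercept":
        slope, intercept = np.polyfit(x, y, 1)
        slope, intercept = float(slope), float(intercept)
    else:
        raise ValueError("mode must be 'through_origin' or 'free_intercept'")
    return CalibrationModel(slope, intercept, r, len(x), mode)


def infer_density_from_widefield(
    model: CalibrationModel, widefield_density: np.ndarray
) -> np.ndarray:
    """Apply the calibration; negative predictions are clipped to 0 with a
    warning (extrapolation below the fitted range)."""
    pred = model.predict(widefield_density)
    if np.any(pred < 0):
        warnings.warn(
            f"{int((pred < 0).sum())} inferred count(s) were negative and "
            "clipped to 0",
            stacklevel=2,
        )
        pred = np.clip(pred, 0, None)
    return pred


# ---------------------------------------------------------------------------
# per-nodule cross-channel correlations
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    r: float
    r_squared: float | None
    p_value: float
    n: int
    method: str


def nodule_signal_correlations(
    table: pd.DataFrame, column_x: str, column_y: str, method: str = "pearson"
) -> CorrelationResult:
    """Correlation of two per-nodule signals (e.g. drug vs carrier uptake,
    drug vs TAM density, signal vs volume) across the nodule table."""
    x = table[column_x].to_numpy(float)
    y = table[column_y].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 nodules with both signals, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            f"constant column ({column_x!r} or {column_y!r}); correlation undefined"
        )
    if method == "pearson":
        res = stats.pearsonr(x, y)
        return CorrelationResult(
            float(res.statistic), float(res.statistic) ** 2, float(res.pvalue),
            len(x), method,
        )
    if method == "spearman":
        res = stats.spearmanr(x, y)
        return CorrelationResult(
            float(res.statistic), None, float(res.pvalue), len(x), method
        )
    raise ValueError("method must be 'pearson' or 'spearman'")
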