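"""Object- and pixel-level colocalization of two markers.

Object level: detected cells from two channels (e.g. a GFP reporter and a
macrophage-avid nanoparticle) are matched one-to-one by nearest-neighbor
distance; the two directed fractions ("what share of GFP+ cells contain
NP", "what share of NP+ cells express GFP") summarize single-cell overlap.
Pixel level: a correlation coefficient of the two channels over a mask,
conventionally restricted to the nodules so that empty parenchyma does not
inflate the value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr, spearmanr

from .segmentation import CellDetections
from .volume import ImageVolume, UndefinedStatisticError

__all__ = ["ColocalizationResult", "single_cell_colocalization", "pixel_correlation"]


@dataclass
class ColocalizationResult:
    fraction_a_with_b: float
    fraction_b_with_a: float
    n_a: int
    n_b: int
    match_radius_um: float
    matches: pd.DataFrame  # index_a, index_b, distance_um


def _positions(cells) -> np.ndarray:
    if isinstance(cells, CellDetections):
        return np.atleast_2d(cells.positions_um) if len(cells) else np.empty((0, 3))
    pts = np.asarray(cells, float)
    return pts.reshape(0, 3) if pts.size == 0 else np.atleast_2d(pts)


def single_cell_colocalization(
    cells_a, cells_b, radius_um: float = 5.0
) -> ColocalizationResult:
    """One-to-one nearest-neighbor matching of two detection sets.

    Candidate pairs within ``radius_um`` are accepted greedily in order of
    increasing distance (ties broken by index order), each cell matched at
    most once.  Empty inputs give fractions of 0 with the counts reported.
    The default radius of one cell radius (5 µm) demands near-coincidence.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    a = _positions(cells_a)
    b = _positions(cells_b)
    empty = pd.DataFrame(columns=["index_a", "index_b", "distance_um"])
    if len(a) == 0 or len(b) == 0:
        return ColocalizationResult(0.0, 0.0, len(a), len(b), radius_um, empty)

    dist = cKDTree(a).sparse_distance_matrix(
        cKDTree(b), radius_um, output_type="coo_matrix"
    )
    if dist.nnz == 0:
        return ColocalizationResult(0.0, 0.0, len(a), len(b), radius_um, empty)
    order = np.lexsort((dist.col, dist.row, dist.data))
    used_a = np.zeros(len(a), bool)
    used_b = np.zeros(len(b), bool)
    rows = []
    for k in order:
        i, j = int(dist.row[k]), int(dist.col[k])
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        rows.append(dict(index_a=i, index_b=j, distance_um=float(dist.data[k])))
    matches = pd.DataFrame(rows, columns=["index_a", "index_b", "distance_um"])
    n_match = len(matches)
    return ColocalizationResult(
        n_match / len(a), n_match / len(b), len(a), len(b), radius_um, matches
    )


def pixel_correlation(
    volume: ImageVolume,
    channel_a: str,
    channel_b: str,
    mask: np.ndarray | None = None,
    method: str = "pearson",
) -> float:
    """Correlation of two channels over the masked voxels.

    ``mask=None`` uses every voxel; in practice pass the nodule mask so the
    coefficient reflects in-tumor co-occurrence.  A constant channel within
    the mask makes the coefficient undefined and raises.
    """
    x = volume.channel(channel_a)
    y = volume.channel(channel_b)
    if mask is None:
        mask = np.ones(x.shape, bool)
    mask = np.asarray(mask, bool)
    if mask.shape != x.shape:
        raise ValueError("mask shape must match the volume")
    if not mask.any():
        raise ValueError("mask is empty")
    xv = x[mask].astype(np.float64)
    yv = y[mask].astype(np.float64)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise UndefinedStatisticError(
            "a channel is constant within the mask; correlation undefined"
        )
    if method == "pearson":
        return float(pearsonr(xv, yv).statistic)
    if method == "spearman":
        return float(spearmanr(xv, yv).statistic)
    raise ValueError("method must be 'pearson' or 'spearman'")
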