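"""Size-normalized cross-sectional intensity profiles and the core/rim ratio.

A nodule's TAM distribution is summarized by casting diameters through the
centroid of its largest cross-section, rescaling each chord to fractional
position 0-100% (both ends on the nodule boundary), and averaging the
background-subtracted nanoparticle intensity into equal-width bins.  The
core/rim ratio compares the central 40-60% window against the peripheral
0-10% plus 90-100% windows; redistribution of TAM from rim to core (the
readout of CSF-1R blockade) raises this ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .segmentation import NoduleLabelMap
from .volume import ImageVolume, UndefinedStatisticError

__all__ = [
    "ProfileCurve",
    "RatioComparison",
    "extract_profile",
    "core_rim_ratio",
    "compare_groups",
]

CORE_WINDOW = (40.0, 60.0)
RIM_WINDOWS = ((0.0, 10.0), (90.0, 100.0))


@dataclass
class ProfileCurve:
    """Binned mean intensity vs fractional position across a nodule (0-100%).

    ``bin_sems`` (optional) are standard errors of the bin means estimated
    from the ray-to-ray scatter; they bound the dynamic range over which
    window ratios are measurable.
    """

    bin_edges: np.ndarray  # length n_bins + 1, percent, 0..100
    bin_means: np.ndarray  # length n_bins, >= 0
    nodule_id: int
    n_rays: int
    bin_sems: np.ndarray | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, float)
        if edges[0] != 0.0 or edges[-1] != 100.0 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must increase from 0 to 100 percent")
        means = np.asarray(self.bin_means, float)
        if len(means) != len(edges) - 1:
            raise ValueError("bin_means length must be n_bins")
        if not np.all(np.isfinite(means)) or np.any(means < 0):
            raise ValueError("bin means must be finite and >= 0")
        if self.bin_sems is not None:
            sems = np.asarray(self.bin_sems, float)
            if len(sems) != len(means) or np.any(~np.isfinite(sems)) or np.any(sems < 0):
                raise ValueError("bin_sems must be finite, >= 0, length n_bins")

    def _window_weights(self, lo: float, hi: float) -> np.ndarray:
        edges = np.asarray(self.bin_edges, float)
        left = np.clip(edges[:-1], lo, hi)
        right = np.clip(edges[1:], lo, hi)
        w = right - left
        if w.sum() <= 0:
            raise ValueError(f"window [{lo}, {hi}]% covers no bins")
        return w / w.sum()

    def window_mean(self, lo: float, hi: float) -> float:
        """Width-weighted mean intensity over the [lo, hi]% window."""
        return float(self._window_weights(lo, hi) @ self.bin_means)

    def window_sem(self, lo: float, hi: float) -> float:
        """Propagated standard error of :meth:`window_mean` (0 if unknown)."""
        if self.bin_sems is None:
            return 0.0
        w = self._window_weights(lo, hi)
        return float(np.sqrt((w**2) @ (np.asarray(self.bin_sems, float) ** 2)))


def extract_profile(
    volume: ImageVolume,
    label_map: NoduleLabelMap,
    nodule_id: int,
    channel: str = "tam_np",
    n_rays: int = 36,
    n_bins: int = 10,
    allow_border: bool = False,
    oversample: int = 4,
    slab_fraction: float = 0.5,
) -> ProfileCurve:
    """Cross-sectional intensity profile of one nodule.

    Profiles are averaged over the central slab of z-slices (those whose
    cross-sectional area is at least ``slab_fraction`` of the maximum —
    averaging several sections through the centre beats a single optical
    section for sparse punctate signal).  On each slice, ``n_rays`` evenly
    spaced diameters are cast through the slice centroid; each is sampled
    boundary-to-boundary (boundary taken from the label map), rescaled to
    0-100% of its chord so tumors of different sizes are comparable, and
    the background-subtracted intensity (background = median of off-nodule
    pixels) is averaged over all rays into ``n_bins`` bins.
    """
    labels = label_map.labels
    if labels.shape != volume.shape:
        raise ValueError("volume and label map must share one grid")
    if not np.any(labels == nodule_id):
        raise ValueError(f"nodule {nodule_id} not present in the label map")
    if label_map.is_border(nodule_id) and not allow_border:
        raise ValueError(
            f"nodule {nodule_id} touches the field border; its profile is "
            "truncated (pass allow_border=True to override)"
        )
    mask3 = labels == nodule_id
    areas = mask3.sum(axis=(1, 2))
    z_max = int(np.argmax(areas))
    z_slab = np.flatnonzero(areas >= slab_fraction * areas[z_max])

    vy, vx = volume.voxel_size[1], volume.voxel_size[2]
    step = min(vy, vx) / oversample
    min_chord = 3.0 * max(vy, vx)
    chan = volume.channel(channel)

    # each diameter (ray) contributes one mean per bin; rays are the
    # independent units for averaging and for the bin-mean standard errors
    ray_sum = np.zeros(n_bins)
    ray_sumsq = np.zeros(n_bins)
    ray_n = np.zeros(n_bins)
    total_rays = 0
    for z in z_slab:
        mask = mask3[z]
        img = chan[z].astype(np.float64)
        outside = labels[z] == 0
        background = float(np.median(img[outside])) if outside.any() else 0.0
        # subtract signed, clip only the final bin means: clipping per-pixel
        # would rectify zero-mean noise into a positive pedestal that swamps
        # faint punctate signal
        signal = img - background

        yy, xx = np.nonzero(mask)
        cy, cx = (yy.mean() + 0.5) * vy, (xx.mean() + 0.5) * vx
        corners_um = np.stack([(yy + 0.5) * vy, (xx + 0.5) * vx], axis=1)
        t_max = float(np.linalg.norm(corners_um - [cy, cx], axis=1).max()) + max(vy, vx)
        n_steps = int(math.ceil(t_max / step))
        t = np.arange(-n_steps, n_steps + 1) * step
        maskf = mask.astype(np.float64)

        theta = np.pi * np.arange(n_rays)[:, None] / n_rays  # (rays, 1)
        ys = (cy + t[None, :] * np.sin(theta)) / vy - 0.5  # (rays, steps)
        xs = (cx + t[None, :] * np.cos(theta)) / vx - 0.5
        inside = (
            ndimage.map_coordinates(
                maskf, [ys.ravel(), xs.ravel()], order=1, cval=0.0
            ).reshape(ys.shape)
            > 0.5
        )
        vals = ndimage.map_coordinates(
            signal, [ys.ravel(), xs.ravel()], order=1, cval=0.0
        ).reshape(ys.shape)
        for k in range(n_rays):
            idx = np.flatnonzero(inside[k])
            if idx.size == 0:
                continue
            i0, i1 = idx[0], idx[-1]
            chord = t[i1] - t[i0]
            if chord < min_chord:
                raise ValueError(
                    f"nodule {nodule_id} is thinner than 3 voxels along the "
                    f"diameter at {math.degrees(math.pi * k / n_rays):.0f}° "
                    f"(z index {z}); profile undefined"
                )
            sel = slice(i0, i1 + 1)
            frac = (t[sel] - t[i0]) / chord  # 0..1 along the chord
            bins = np.minimum((frac * n_bins).astype(int), n_bins - 1)
            s = np.zeros(n_bins)
            c = np.zeros(n_bins)
            np.add.at(s, bins, vals[k, sel])
            np.add.at(c, bins, 1.0)
            got = c > 0
            m = np.zeros(n_bins)
            m[got] = s[got] / c[got]
            ray_sum[got] += m[got]
            ray_sumsq[got] += m[got] ** 2
            ray_n[got] += 1
            total_rays += 1
    if not np.all(ray_n > 1):
        raise ValueError(f"profile of nodule {nodule_id} has empty bins")
    means = ray_sum / ray_n
    var = np.clip(ray_sumsq / ray_n - means**2, 0, None) * ray_n / (ray_n - 1)
    sems = np.sqrt(var / ray_n)
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    return ProfileCurve(
        edges, np.clip(means, 0, None), nodule_id, total_rays, bin_sems=sems
    )


def core_rim_ratio(profile: ProfileCurve) -> float:
    """Mean intensity over the 40-60% core window divided by the mean over
    the 0-10% + 90-100% rim windows.

    When the profile carries bin uncertainties, a rim mean below its own
    standard error is floored at that error: a rim statistically
    indistinguishable from zero bounds the ratio at the profile's measurable
    dynamic range rather than letting it diverge.  Without uncertainties, a
    zero rim with a nonzero core gives +inf (flagged via a warning); both
    windows zero is undefined and raises.
    """
    core = profile.window_mean(*CORE_WINDOW)
    rim_vals = [profile.window_mean(lo, hi) for lo, hi in RIM_WINDOWS]
    rim = float(np.mean(rim_vals))
    rim_sem = float(
        np.sqrt(sum(profile.window_sem(lo, hi) ** 2 for lo, hi in RIM_WINDOWS))
        / len(RIM_WINDOWS)
    )
    if rim < rim_sem:
        rim = rim_sem
    if rim == 0.0 and core == 0.0:
        raise UndefinedStatisticError("core and rim windows are both zero")
    if rim == 0.0:
        warnings.warn("rim mean is zero; core/rim ratio is +inf", stacklevel=2)
        return math.inf
    return core / rim


@dataclass
class RatioComparison:
    """Two-group comparison of per-nodule core/rim ratios."""

    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    df: float
    n_a: int
    n_b: int
    variant: str


def compare_groups(
    ratios_a, ratios_b, variant: str = "student"
) -> RatioComparison:
    """Unpaired two-tailed t-test between two groups of ratios.

    ``variant='student'`` pools variances (the conventional unpaired test);
    ``'welch'`` drops the equal-variance assumption.  Zero variance in both
    groups with equal means yields t=0, p=1 by convention; zero variance
    with unequal means is degenerate and raises.
    """
    a = np.asarray(ratios_a, float)
    b = np.asarray(ratios_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("ratios must be finite")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            df = len(a) + len(b) - 2
            return RatioComparison(
                float(a.mean()), float(b.mean()), 0.0, 1.0, float(df),
                len(a), len(b), variant,
            )
        raise UndefinedStatisticError(
            "zero variance in both groups with unequal means; t undefined"
        )
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return RatioComparison(
        float(a.mean()), float(b.mean()), float(res.statistic), float(res.pvalue),
        float(res.df), len(a), len(b), variant,
    )
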