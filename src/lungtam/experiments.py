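"""Benchmark experiments exercising the pipeline end-to-end on synthetic
ground truth.

Each function simulates its own data from a seed, runs the relevant part of
the analysis, and returns a dict of summary quantities.  The problem sizes
(field extents, voxel pitches, nodule counts, replicate counts) are the
package's reference study conditions; they are chosen so each experiment
gives stable statistics at desk scale.
"""

from __future__ import annotations

import shutil
import tempfile
import time
from hashlib import sha256
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .config import RunConfig
from .pipeline import run_pipeline
from .quantification import (
    compute_tam_density,
    compute_tumor_burden,
    fit_calibration,
    nodule_footprints,
    widefield_integrated_density,
)
from .segmentation import detect_cells, segment_nodules, segmentation_concordance
from .spatial import compare_groups, core_rim_ratio, extract_profile
from .synthetic import (
    NodulePlacementError,
    SimulationConfig,
    generate_lung_volume,
    render_widefield,
    simulate_coloc_pair,
    simulate_single_nodule,
)
from .colocalization import single_cell_colocalization

__all__ = [
    "volume_recovery_experiment",
    "density_recovery_experiment",
    "calibration_experiment",
    "core_rim_experiment",
    "coloc_experiment",
    "concordance_experiment",
    "widefield_rank_experiment",
    "determinism_experiment",
]


def _child_seeds(seed: int, n: int, salt: int = 0) -> list[int]:
    """Independent 31-bit seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(900 + salt,))
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def _generate(cfg: SimulationConfig, retries: int = 8):
    """Generate a field, re-rolling the seed when the random packing of an
    unlucky draw cannot place every nodule.  Deterministic per seed."""
    for k in range(retries):
        try:
            return generate_lung_volume(
                cfg if k == 0 else SimulationConfig(
                    **{**cfg.__dict__, "seed": (cfg.seed + 7_654_321 * k) % 2**31}
                )
            )
        except NodulePlacementError:
            if k == retries - 1:
                raise
    raise AssertionError("unreachable")


def _match_by_centroid(truth: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Greedy one-to-one matching of true and segmented nodules by distance."""
    tc = truth[["cz_um", "cy_um", "cx_um"]].to_numpy()
    sc = table[["cz_um", "cy_um", "cx_um"]].to_numpy()
    d = np.linalg.norm(tc[:, None, :] - sc[None, :, :], axis=2)
    pairs = []
    used_t, used_s = set(), set()
    for k in np.argsort(d, axis=None):
        i, j = divmod(int(k), d.shape[1])
        if i in used_t or j in used_s:
            continue
        used_t.add(i)
        used_s.add(j)
        pairs.append((i, j, d[i, j]))
        if len(used_t) == min(d.shape):
            break
    rows = []
    for i, j, dist in pairs:
        rows.append(
            dict(
                true_id=int(truth.id.iloc[i]),
                seg_id=int(table.nodule_id.iloc[j]),
                centroid_dist_um=float(dist),
                true_volume_mm3=float(truth.volume_mm3.iloc[i]),
                seg_volume_mm3=float(table.volume_mm3.iloc[j]),
                true_count=int(truth.tam_count.iloc[i]),
                seg_count=int(table.tam_count.iloc[j]),
                true_density_mm3=float(truth.tam_density_mm3.iloc[i]),
                seg_density_mm3=float(table.tam_density_mm3.iloc[j]),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 1. segmentation volume recovery
# ---------------------------------------------------------------------------


def volume_recovery_experiment(seed: int = 0) -> dict:
    """Segment a 10-nodule lung (radii 50-300 µm, contrast 5, SNR 10) and
    compare per-nodule volumes and total burden against ground truth."""
    t0 = time.perf_counter()
    cfg = SimulationConfig(
        field_size_um=(800.0, 2000.0, 2000.0),
        voxel_size_um=(5.0, 5.0, 5.0),
        n_nodules=10,
        nodule_radius_range_um=(50.0, 300.0),
        nodule_contrast=5.0,
        snr=10.0,
        seed=seed,
    )
    volume, truth = _generate(cfg)
    label_map = segment_nodules(volume, "nuclear")
    burden = compute_tumor_burden(label_map)
    table = compute_tam_density(label_map, detect_cells(volume, "tam_np"))
    tf = truth.nodules_frame().rename(
        columns={"cx_um": "cx_um", "cy_um": "cy_um", "cz_um": "cz_um"}
    )
    matched = _match_by_centroid(tf, table)
    vol_err = 100 * np.abs(matched.seg_volume_mm3 / matched.true_volume_mm3 - 1)
    total_true = float(tf.volume_mm3.sum())
    return dict(
        n_true=len(tf),
        n_detected=int(len(matched)),
        n_segmented=int(burden.n_nodules),
        max_volume_error_pct=float(vol_err.max()),
        median_volume_error_pct=float(vol_err.median()),
        total_burden_mm3=float(burden.total_mm3),
        total_burden_error_pct=float(
            100 * abs(burden.total_mm3 / total_true - 1)
        ),
        runtime_s=time.perf_counter() - t0,
    )


# ---------------------------------------------------------------------------
# 2. TAM density recovery
# ---------------------------------------------------------------------------


def density_recovery_experiment(seed: int = 0, n_fields: int = 2) -> dict:
    """Recover per-nodule TAM densities seeded log-uniformly over
    8,000-60,000 mm^-3 at SNR 10, counting at 3 µm voxel pitch."""
    t0 = time.perf_counter()
    frames = []
    for s in _child_seeds(seed, n_fields, salt=2):
        cfg = SimulationConfig(
            field_size_um=(700.0, 1400.0, 1400.0),
            voxel_size_um=(3.0, 3.0, 3.0),
            n_nodules=8,
            nodule_radius_range_um=(110.0, 190.0),
            snr=10.0,
            seed=s,
        )
        volume, truth = _generate(cfg)
        label_map = segment_nodules(volume, "nuclear")
        table = compute_tam_density(label_map, detect_cells(volume, "tam_np"))
        frames.append(_match_by_centroid(truth.nodules_frame(), table))
    matched = pd.concat(frames, ignore_index=True)
    err = 100 * np.abs(matched.seg_density_mm3 / matched.true_density_mm3 - 1)
    return dict(
        n_nodules=len(matched),
        fraction_within_10pct=float((err <= 10).mean()),
        max_density_error_pct=float(err.max()),
        median_density_error_pct=float(err.median()),
        mean_recovered_density_mm3=float(matched.seg_density_mm3.mean()),
        runtime_s=time.perf_counter() - t0,
    )


# ---------------------------------------------------------------------------
# 3. wide-field calibration property
# ---------------------------------------------------------------------------


def calibration_experiment(
    seed: int = 0, n_replicates: int = 50, n_pairs: int = 30
) -> dict:
    """Fit the conversion factor on synthetic (density, count) pairs.

    Wide-field density is generated proportional to cell count with 20%
    multiplicative noise; the replicate pass rate of Pearson r >= 0.9 and
    the through-origin slope recovery at 5% noise are reported.
    """
    t0 = time.perf_counter()
    c = 0.02  # fluorescence-density units per cell
    rs = []
    for s in _child_seeds(seed, n_replicates, salt=3):
        rng = np.random.default_rng(s)
        counts = np.exp(rng.uniform(np.log(100), np.log(5000), n_pairs))
        density = c * counts * (1 + 0.20 * rng.normal(size=n_pairs))
        density = np.clip(density, 1e-9, None)
        rs.append(fit_calibration(density, counts).pearson_r)
    rs = np.asarray(rs)

    rng = np.random.default_rng(_child_seeds(seed, 1, salt=4)[0])
    counts = np.exp(rng.uniform(np.log(100), np.log(5000), n_pairs))
    density = c * counts * (1 + 0.05 * rng.normal(size=n_pairs))
    model = fit_calibration(density, counts)
    return dict(
        n_replicates=n_replicates,
        pass_rate_r_ge_0p9=float((rs >= 0.9).mean()),
        median_pearson_r=float(np.median(rs)),
        slope_error_pct_at_5pct_noise=float(100 * abs(model.slope * c - 1)),
        runtime_s=time.perf_counter() - t0,
    )


# ---------------------------------------------------------------------------
# 4. core/rim statistic validity
# ---------------------------------------------------------------------------


def _cohort_ratios(
    mode: str, n: int, seeds: list[int], radius_um: float, density_mm3: float,
    bias: float, snr: float,
) -> np.ndarray:
    ratios = np.empty(n)
    for i in range(n):
        volume, _ = simulate_single_nodule(
            radius_um=radius_um, density_mm3=density_mm3, mode=mode, bias=bias,
            snr=snr, voxel_um=5.0, margin_um=30.0, seed=seeds[i],
            channels=("nuclear", "tam_np"),
        )
        label_map = segment_nodules(volume, "nuclear")
        prof = extract_profile(volume, label_map, 1)
        ratios[i] = core_rim_ratio(prof)
    # +inf can occur when the rim estimate hits zero; cap for group stats
    return np.minimum(ratios, 1e6)


def core_rim_experiment(
    seed: int = 0,
    n_replicates: int = 50,
    n_per_group: int = 14,
    radius_um: float = 100.0,
    density_mm3: float = 30_000.0,
    bias: float = 2.0,
    snr: float = 10.0,
) -> dict:
    """Monte-Carlo validity of the core/rim statistic.

    Power arm: rim-biased vs core-biased cohorts (n=14 each); the fraction
    of replicates with correct mean ordering and with unpaired-t p < 0.05.
    Null arm: uniform vs uniform cohorts; the rejection rate at alpha=0.05.
    """
    t0 = time.perf_counter()
    ordering, signif, null_reject = [], [], []
    seeds = _child_seeds(seed, n_replicates * 4 * n_per_group, salt=5)
    k = 0
    for _ in range(n_replicates):
        take = lambda: [seeds[j] for j in range(k, k + n_per_group)]  # noqa: E731
        rim = _cohort_ratios("rim", n_per_group, take(), radius_um,
                             density_mm3, bias, snr)
        k += n_per_group
        core = _cohort_ratios("core", n_per_group, take(), radius_um,
                              density_mm3, bias, snr)
        k += n_per_group
        cmp = compare_groups(core, rim)
        ordering.append(cmp.mean_a > cmp.mean_b)
        signif.append(cmp.p_value < 0.05)
        u1 = _cohort_ratios("uniform", n_per_group, take(), radius_um,
                            density_mm3, bias, snr)
        k += n_per_group
        u2 = _cohort_ratios("uniform", n_per_group, take(), radius_um,
                            density_mm3, bias, snr)
        k += n_per_group
        null_reject.append(compare_groups(u1, u2).p_value < 0.05)
    return dict(
        n_replicates=n_replicates,
        ordering_rate=float(np.mean(ordering)),
        power=float(np.mean(signif)),
        null_rejection_rate=float(np.mean(null_reject)),
        runtime_s=time.perf_counter() - t0,
    )


# ---------------------------------------------------------------------------
# 6. colocalization recovery
# ---------------------------------------------------------------------------


def coloc_experiment(
    seed: int = 0, n_cells: int = 250, subset_fraction: float = 0.8,
    snr: float = 10.0,
) -> dict:
    """Recover known object-level overlap: channel B is an exact 80% subset
    of channel A, so the true fractions are (0.80, 1.00)."""
    t0 = time.perf_counter()
    volume, pts_a, pts_b = simulate_coloc_pair(
        n_cells=n_cells, subset_fraction=subset_fraction, snr=snr, seed=seed
    )
    det_a = detect_cells(volume, "cells_a")
    det_b = detect_cells(volume, "cells_b")
    res = single_cell_colocalization(det_a, det_b, radius_um=5.0)
    return dict(
        n_true_a=len(pts_a),
        n_true_b=len(pts_b),
        n_detected_a=res.n_a,
        n_detected_b=res.n_b,
        fraction_a_with_b=res.fraction_a_with_b,
        fraction_b_with_a=res.fraction_b_with_a,
        runtime_s=time.perf_counter() - t0,
    )


# ---------------------------------------------------------------------------
# 7. dual-channel segmentation concordance
# ---------------------------------------------------------------------------


def concordance_experiment(seed: int = 0, snr: float = 30.0) -> dict:
    """Segment the same synthetic lung independently on the nuclear and
    tumor-reporter channels and rank-correlate matched nodule volumes."""
    t0 = time.perf_counter()
    cfg = SimulationConfig(
        field_size_um=(700.0, 1200.0, 1200.0),
        n_nodules=8,
        nodule_radius_range_um=(60.0, 180.0),
        snr=snr,
        seed=seed,
    )
    volume, _ = _generate(cfg)
    map_a = segment_nodules(volume, "nuclear")
    map_b = segment_nodules(volume, "tumor_reporter")
    res = segmentation_concordance(map_a, map_b)
    return dict(
        spearman_rho=res.spearman_rho,
        n_matched=res.n_matched,
        runtime_s=time.perf_counter() - t0,
    )


# ---------------------------------------------------------------------------
# paired wide-field / high-resolution rank agreement (image-level)
# ---------------------------------------------------------------------------


def widefield_rank_experiment(seed: int = 0, n_fields: int = 3) -> dict:
    """Image-level check that wide-field integrated density ranks nodules
    like their segmented TAM counts (similar-size nodules, as in surveys
    comparing infiltrate across comparable tumors)."""
    t0 = time.perf_counter()
    dens_all, counts_all = [], []
    for s in _child_seeds(seed, n_fields, salt=7):
        cfg = SimulationConfig(
            field_size_um=(700.0, 1600.0, 1600.0),
            n_nodules=10,
            nodule_radius_range_um=(130.0, 170.0),
            snr=10.0,
            seed=s,
        )
        volume, _ = _generate(cfg)
        label_map = segment_nodules(volume, "nuclear")
        table = compute_tam_density(label_map, detect_cells(volume, "tam_np"))
        wf = render_widefield(volume, 4, 10.0)
        feet = nodule_footprints(label_map, 4)[: wf.shape[0], : wf.shape[1]]
        dens = widefield_integrated_density(wf, feet, "tam_np")
        pairs = dens.merge(table[["nodule_id", "tam_count"]], on="nodule_id")
        dens_all += pairs.integrated_density.tolist()
        counts_all += pairs.tam_count.tolist()
    rho = float(spearmanr(dens_all, counts_all).statistic)
    model = fit_calibration(np.asarray(dens_all), np.asarray(counts_all, float))
    return dict(
        n_pairs=len(dens_all),
        spearman_rho=rho,
        pearson_r=model.pearson_r,
        runtime_s=time.perf_counter() - t0,
    )


# ---------------------------------------------------------------------------
# 8. pipeline determinism
# ---------------------------------------------------------------------------


def determinism_experiment(seed: int = 0) -> dict:
    """Run the full pipeline twice with one config+seed and compare every
    output table byte-for-byte."""
    t0 = time.perf_counter()
    digests = []
    for _ in range(2):
        tmp = Path(tempfile.mkdtemp(prefix="lungtam_det_"))
        try:
            cfg = RunConfig(
                seed=seed,
                out_dir=tmp,
                simulation=dict(
                    field_size_um=[500.0, 900.0, 900.0],
                    n_nodules=3,
                    nodule_radius_range_um=[80.0, 150.0],
                ),
            )
            run_pipeline(cfg)
            digests.append(
                {
                    p.name: sha256(p.read_bytes()).hexdigest()
                    for p in sorted(tmp.glob("*.csv")) + sorted(tmp.glob("*.json"))
                }
            )
        finally:
            shutil.rmtree(tmp, ignore_errors=True)
    return dict(
        identical=bool(digests[0] == digests[1]),
        n_files=len(digests[0]),
        runtime_s=time.perf_counter() - t0,
    )
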