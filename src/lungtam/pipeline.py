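"""End-to-end pipeline: simulate (or load) → segment → detect → quantify →
calibrate → profile → colocalize, with every table written under one output
directory.  Outputs are deterministic: identical config + seed reproduces
byte-identical CSV/JSON files."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .colocalization import pixel_correlation
from .config import RunConfig
from .quantification import (
    compute_tam_density,
    compute_tumor_burden,
    fit_calibration,
    nodule_footprints,
    widefield_integrated_density,
)
from .segmentation import SegmentationParams, detect_cells, segment_nodules
from .spatial import core_rim_ratio, extract_profile
from .synthetic import generate_lung_volume, render_widefield
from .volume import UndefinedStatisticError

__all__ = ["run_pipeline"]

log = logging.getLogger("lungtam.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending object."""


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every enabled stage in dependency order.

    Returns a summary dict (also written to ``summary.json``); all tables
    land under ``config.out_dir``.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    provenance = dict(config_hash=chash, seed=config.seed)
    summary: dict = dict(provenance)

    # -- acquire ------------------------------------------------------------
    ground_truth = None
    if config.input_volume is not None:
        volume = lio.read_volume(config.input_volume)
        log.info("loaded volume %s: shape=%s", config.input_volume, volume.shape)
    else:
        sim = config.simulation_config()
        log.info("simulating field: %s", asdict(sim))
        volume, ground_truth = generate_lung_volume(sim)
        lio.write_table(ground_truth.nodules_frame(), out / "true_nodules.csv")
        lio.write_table(ground_truth.cells, out / "true_cells.csv")

    # -- segment ------------------------------------------------------------
    seg = config.segmentation
    params = SegmentationParams(
        smoothing_sigma_um=seg.smoothing_sigma_um,
        threshold_rule=seg.threshold_rule,
        k=seg.k,
        min_nodule_volume_mm3=seg.min_nodule_volume_mm3,
        connectivity=seg.connectivity,
        fill_holes=seg.fill_holes,
    )
    try:
        label_map = segment_nodules(volume, seg.channel, params)
    except Exception as e:
        raise PipelineError(f"segmentation failed on channel {seg.channel!r}: {e}") from e
    log.info("segmented %d nodules (params=%s)", label_map.n_nodules, params)
    lio.write_label_map(label_map, out / "label_map")

    burden = compute_tumor_burden(label_map)
    summary["n_nodules"] = burden.n_nodules
    summary["total_burden_mm3"] = round(burden.total_mm3, 8)

    # -- detect -------------------------------------------------------------
    det = config.detection
    try:
        detections = detect_cells(
            volume, det.channel, det.cell_radius_um, det.threshold_k,
            det.min_separation_um,
        )
    except Exception as e:
        raise PipelineError(f"cell detection failed on {det.channel!r}: {e}") from e
    log.info("detected %d cells on %r (params=%s)", len(detections), det.channel,
             detections.params)
    lio.write_table(detections.frame(), out / "detections.csv")

    # -- quantify -----------------------------------------------------------
    try:
        table = compute_tam_density(label_map, detections, volume)
    except Exception as e:
        raise PipelineError(f"quantification failed: {e}") from e
    lio.write_table(table, out / "nodule_table.csv")
    summary["n_detections"] = len(detections)
    summary["n_peritumoral"] = table.attrs["n_peritumoral"]
    if len(table):
        summary["mean_tam_density_mm3"] = round(float(table.tam_density_mm3.mean()), 3)

    # -- wide-field calibration --------------------------------------------
    if config.widefield.enabled and len(table) >= 3:
        wf_cfg = config.widefield
        wf = render_widefield(volume, wf_cfg.downsample_factor, wf_cfg.blur_sigma_um)
        feet = nodule_footprints(label_map, wf_cfg.downsample_factor)
        # crop mismatch from block reduction
        feet = feet[: wf.shape[0], : wf.shape[1]]
        try:
            dens = widefield_integrated_density(wf, feet, det.channel)
            pairs = dens.merge(table[["nodule_id", "tam_count"]], on="nodule_id")
            model = fit_calibration(
                pairs.integrated_density.to_numpy(),
                pairs.tam_count.to_numpy(float),
                wf_cfg.calibration_mode,
            )
            cal = dict(provenance, slope=model.slope, intercept=model.intercept,
                       pearson_r=model.pearson_r, n_pairs=model.n_pairs,
                       mode=model.mode)
            summary["calibration_pearson_r"] = round(model.pearson_r, 6)
            lio.write_table(pairs, out / "widefield_pairs.csv")
        except UndefinedStatisticError as e:
            cal = dict(provenance, error=str(e))
        _json_dump(cal, out / "calibration.json")

    # -- profiles and core/rim ratios ---------------------------------------
    if config.profile.enabled:
        prof_rows, ratio_rows = [], []
        for nid in label_map.nodule_ids():
            nid = int(nid)
            if label_map.is_border(nid):
                log.info("skipping border nodule %d for profiling", nid)
                continue
            try:
                prof = extract_profile(
                    volume, label_map, nid, config.profile.channel,
                    config.profile.n_rays, config.profile.n_bins,
                )
            except ValueError as e:
                log.info("no profile for nodule %d: %s", nid, e)
                continue
            for lo, hi, m in zip(prof.bin_edges[:-1], prof.bin_edges[1:],
                                 prof.bin_means):
                prof_rows.append(dict(nodule_id=nid, bin_lo_pct=lo, bin_hi_pct=hi,
                                      mean_intensity=m))
            try:
                ratio = core_rim_ratio(prof)
            except UndefinedStatisticError:
                ratio = float("nan")
            ratio_rows.append(dict(nodule_id=nid, core_rim_ratio=ratio))
        lio.write_table(
            pd.DataFrame(prof_rows, columns=["nodule_id", "bin_lo_pct",
                                             "bin_hi_pct", "mean_intensity"]),
            out / "profiles.csv",
        )
        lio.write_table(
            pd.DataFrame(ratio_rows, columns=["nodule_id", "core_rim_ratio"]),
            out / "core_rim_ratios.csv",
        )
        finite = [r["core_rim_ratio"] for r in ratio_rows
                  if np.isfinite(r["core_rim_ratio"])]
        if finite:
            summary["mean_core_rim_ratio"] = round(float(np.mean(finite)), 6)

    # -- pixel colocalization ----------------------------------------------
    if config.colocalization.enabled:
        cc = config.colocalization
        try:
            r = pixel_correlation(volume, cc.channel_a, cc.channel_b,
                                  label_map.labels > 0, cc.method)
            coloc = dict(provenance, method=cc.method, channel_a=cc.channel_a,
                         channel_b=cc.channel_b, correlation=round(r, 6),
                         mask="nodules")
            summary["pixel_colocalization_r"] = round(r, 6)
        except (UndefinedStatisticError, ValueError) as e:
            coloc = dict(provenance, error=str(e))
        _json_dump(coloc, out / "colocalization.json")

    if ground_truth is not None:
        summary["n_true_nodules"] = len(ground_truth.nodules)
    _json_dump(summary, out / "summary.json")
    log.info("pipeline complete: %s", summary)
    return summary
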