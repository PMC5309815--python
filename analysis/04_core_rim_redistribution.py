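#!/usr/bin/env python
"""Core/rim analysis of TAM spatial redistribution.

Builds two cohorts of n=14 single-nodule fields — rim-biased infiltration
(the untreated phenotype) vs core-biased (the CSF-1R-blockade phenotype) —
extracts size-normalized nanoparticle intensity profiles, computes per-
nodule core/rim ratios, and compares the groups with an unpaired t-test.
Writes results/analysis/core_rim_groups.csv and core_rim_test.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from lungtam import (
    compare_groups,
    core_rim_ratio,
    extract_profile,
    segment_nodules,
    simulate_single_nodule,
)
from lungtam.io import write_table

RESULTS = Path("results/analysis")
N_PER_GROUP = 14


def cohort(mode: str, base_seed: int) -> np.ndarray:
    ratios = []
    for i in range(N_PER_GROUP):
        volume, _ = simulate_single_nodule(
            radius_um=100.0, density_mm3=30_000.0, mode=mode, bias=2.0,
            snr=10.0, voxel_um=5.0, margin_um=30.0, seed=base_seed + i,
            channels=("nuclear", "tam_np"),
        )
        label_map = segment_nodules(volume, "nuclear")
        prof = extract_profile(volume, label_map, 1)
        ratios.append(core_rim_ratio(prof))
    return np.asarray(ratios)


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    rim = cohort("rim", 41_000)
    core = cohort("core", 42_000)
    groups = pd.DataFrame(
        dict(
            group=["rim"] * N_PER_GROUP + ["core"] * N_PER_GROUP,
            core_rim_ratio=np.concatenate([rim, core]),
        )
    )
    write_table(groups, RESULTS / "core_rim_groups.csv")
    res = compare_groups(core, rim)
    out = dict(
        n_per_group=N_PER_GROUP,
        mean_core_biased=round(res.mean_a, 3),
        mean_rim_biased=round(res.mean_b, 3),
        t_statistic=round(res.t_statistic, 3),
        p_value=float(f"{res.p_value:.3g}"),
        variant=res.variant,
    )
    (RESULTS / "core_rim_test.json").write_text(
        json.dumps(out, indent=2, sort_keys=True) + "\n"
    )
    print(json.dumps(out, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
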