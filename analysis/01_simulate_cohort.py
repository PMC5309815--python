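#!/usr/bin/env python
"""Simulate a small cohort of ground-truthed cleared-lung fields.

Writes the per-field ground-truth tables under results/analysis/cohort/ and
the image volumes (large, binary) under scratch/cohort/.  Downstream
drivers re-simulate deterministically from the same seeds, so the volumes
on disk are a convenience, not a dependency.
"""

from pathlib import Path

from lungtam import SimulationConfig, generate_lung_volume
from lungtam.io import write_table, write_volume

RESULTS = Path("results/analysis/cohort")
SCRATCH = Path("scratch/cohort")
SEEDS = (101, 102, 103)


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    for seed in SEEDS:
        cfg = SimulationConfig(
            field_size_um=(700.0, 1400.0, 1400.0),
            voxel_size_um=(3.5, 3.5, 3.5),  # counting-grade sampling
            n_nodules=8,
            nodule_radius_range_um=(90.0, 190.0),
            seed=seed,
        )
        volume, truth = generate_lung_volume(cfg)
        write_volume(volume, SCRATCH / f"lung_{seed}")
        write_table(truth.nodules_frame(), RESULTS / f"lung_{seed}_nodules.csv")
        # per-cell tables are bulky and fully regenerable: keep with volumes
        write_table(truth.cells, SCRATCH / f"lung_{seed}_cells.csv")
        df = truth.nodules_frame()
        print(
            f"lung {seed}: {len(df)} nodules, total volume "
            f"{df.volume_mm3.sum():.4f} mm^3, TAM density "
            f"{df.tam_density_mm3.min():.0f}-{df.tam_density_mm3.max():.0f} mm^-3"
        )


if __name__ == "__main__":
    main()
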