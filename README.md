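# lungtam

Quantitative image analysis of tumor nodules and tumor-associated
macrophages (TAM) in multi-channel 3D fluorescence volumes of optically
cleared whole lungs — with a ground-truthed synthetic-volume generator so
every statistic can be validated end-to-end.

Optical clearing makes an entire mouse lung transparent enough to image at
cellular resolution, turning tumor immunology questions into image-analysis
questions: How many nodules, and how big (tumor burden)? How many
macrophages per mm³ of tumor, and how variable is that across nodules? Do
TAM sit at the tumor rim or its core, and does a CSF-1R inhibitor shift
them? Does an injected nanoparticle actually label TAM, and does drug
delivery track TAM density? This package implements those measurements for
anyone working with cleared-organ volumes (or realistic simulations of
them).

## What it computes

| Quantity | How |
| --- | --- |
| Nodule label map | Gaussian smoothing → global threshold (Otsu or median+k·MAD) on the nuclear channel → 26-connected components ≥ 2×10⁻⁵ mm³ |
| Tumor burden | per-nodule volume = voxel count × voxel volume (mm³); total over nodules |
| TAM count / density | Laplacian-of-Gaussian blob detection at the cell scale (σ = r/√3), median+6·MAD threshold, non-maximum suppression at one cell radius; density = count / nodule volume (cells·mm⁻³) |
| Wide-field calibration | integrated fluorescence density (background-subtracted sum per µm² of projected footprint) fitted through the origin against segmented counts; Pearson r reported; the conversion factor then infers counts from overview images alone |
| Core/rim ratio | size-normalized cross-sectional intensity profile (diameters through the central slab, 10 bins); ratio = mean(40–60%) / mean(0–10% ∪ 90–100%); groups compared by unpaired t-test |
| Colocalization | one-to-one nearest-neighbor matching of two detection sets within 5 µm (directed fractions), and masked pixel correlation |
| Concordance | Spearman ρ of matched per-nodule volumes from two independently segmented channels |

All outputs use physical units: µm for coordinates, mm³ for volumes,
cells·mm⁻³ for densities.

## Worked example

```python
from lungtam import (SimulationConfig, generate_lung_volume, segment_nodules,
                     detect_cells, compute_tam_density)

cfg = SimulationConfig(
    field_size_um=(700, 1400, 1400),   # z, y, x in µm
    voxel_size_um=(3.5, 3.5, 3.5),     # counting-grade sampling
    n_nodules=8,
    nodule_radius_range_um=(90, 190),
    seed=101,
)
volume, truth = generate_lung_volume(cfg)          # 3 channels + ground truth
label_map = segment_nodules(volume, "nuclear")     # 8 nodules
detections = detect_cells(volume, "tam_np")        # TAM as points (µm)
table = compute_tam_density(label_map, detections)
print(table[["nodule_id", "volume_mm3", "tam_count", "tam_density_mm3"]])
```

which prints (seed 101):

```
   nodule_id  volume_mm3  tam_count  tam_density_mm3
0          1    0.010828        129     11913.703917
1          2    0.002895         93     32126.191681
2          3    0.005039        133     26394.282304
3          4    0.025971        267     10280.826850
4          5    0.003667        118     32175.392975
5          6    0.003597        133     36975.276433
6          7    0.002920         24      8220.017678
7          8    0.002998         52     17344.697724
```

Eight nodules of 0.003–0.026 mm³ carrying 8,200–37,000 TAM mm⁻³ — the
several-fold spread across similar-sized nodules that makes per-nodule
(rather than per-organ) quantification worthwhile. The seeded ground-truth
densities for this field span 8,900–39,500 mm⁻³: recovered values track
truth to a few percent.

The same steps are available from the shell:

```bash
lungtam run --seed 101 --out results/run101          # full pipeline
lungtam simulate --seed 7 --out sim/                 # just the generator
lungtam segment sim/volume --out sim/labels          # single stages
lungtam coloc sim/volume --channel-a tam_np --channel-b tumor_reporter
```

## Analysis drivers

`analysis/` holds numbered scripts that reproduce the study-style analyses
over simulated cohorts and write their tables under `results/analysis/`:

1. `01_simulate_cohort.py` — three ground-truthed lungs (volumes land in
   `scratch/`, truth tables in `results/`)
2. `02_quantify_tumors.py` — burden, TAM densities, nuclear/reporter
   segmentation concordance
3. `03_widefield_calibration.py` — wide-field ↔ cell-count conversion
4. `04_core_rim_redistribution.py` — rim-biased vs core-biased cohorts
   (n = 14 each), core/rim ratios, unpaired t-test
5. `05_colocalization.py` — object fractions and cell-scale pixel
   correlation for two channels with 80% shared cells

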