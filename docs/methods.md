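# Methods

`lungtam` quantifies tumor nodules and tumor-associated macrophages (TAM) in
multi-channel 3D fluorescence volumes of optically cleared whole lungs. The
analyses it implements — nodule segmentation from nuclear-density contrast,
TAM counting and density estimation, wide-field↔cell-count calibration,
size-normalized core/rim profiling, and colocalization — are standard
readouts for studies of myeloid infiltration in murine lung-tumor models.
Because raw whole-lung datasets of this kind are rarely deposited, the
package ships a ground-truthed synthetic-volume generator, and every
statistic is validated end-to-end against known truth.

## Synthetic volumes

A field is a box of physical size `field_size_um` sampled at `voxel_size_um`
(axis order z, y, x; z pitch may differ). Channels:

- **nuclear** — flat parenchyma background `B` (default 100 intensity units)
  plus `(contrast − 1)·B` inside every nodule. The default contrast of 5
  encodes the strong cellular-density elevation that makes lung tumors
  segmentable from a nuclear stain alone.
- **tumor_reporter** — a GFP-like channel supported exactly on the nodules
  before blur; used for dual-channel concordance checks.
- **tam_np** — TAM rendered as Gaussian puncta (default radius 5 µm, the
  scale of a macrophage; sigma = radius/2) over a background equal to `B`.
  Overlapping puncta add. Punctum peaks are calibrated after blur against a
  discrete delta-response so an isolated punctum peaks at exactly
  `snr · sigma_noise`.
- optional **carrier**/**drug** — uniform per-nodule levels proportional to
  that nodule's TAM density with 5% multiplicative noise, emulating
  macrophage-mediated nanoparticle drug delivery.

Nodules are ellipsoids with semi-axes drawn as radius × Uniform(0.85, 1.18)
and random orientation; ellipsoids trade the irregular margins of real
nodules for exact analytic volumes, which every downstream oracle relies
on. Placement is greedy rejection sampling, largest nodule first, with a
conservative bounding-sphere overlap test and a 20 µm margin; an over-crowded
field raises an error naming the nodule that failed.

TAM positions are sampled per nodule with a Poisson count of mean
density × volume and a radial law selected by `tam_spatial_mode`: uniform in
the ellipsoid, rim-biased (density ∝ r^bias, inverse-CDF sampled), or
core-biased (∝ (1−r)^bias, rejection sampled). Rim/core bias of 2 is the
reference strength for treatment-contrast experiments. Per-nodule densities
are drawn **log-uniformly** over 8,000–60,000 cells mm⁻³. The distribution
family is a modeling choice — only the range and the ~20,000 mm⁻³ scale of
the average are constrained by what is known of KP-model lung tumors — and
log-uniform spreads nodules evenly across the order-of-magnitude range.
The recorded "true density" is the realized count divided by the analytic
volume, so count = density × volume holds exactly.

Optics and noise: a separable Gaussian PSF (default sigma 1.5 µm lateral,
2.5 µm axial) blurs every channel; Gaussian shot-like noise with variance
`read² + gain·signal` is then added and clipped at zero. One `snr` knob sets
the noise scale: `snr = (contrast−1)·B / sigma_noise(B)`, with half the
background variance assigned to the signal-dependent term. Channel
backgrounds sit well above the noise floor so zero-clipping never sculpts
the noise distribution. `snr=None` disables noise. Reproducibility: every
nodule and every channel's noise uses its own `SeedSequence` child stream
keyed by `(seed, purpose, index)`, so outputs are bit-identical for a given
config+seed and adding a nodule or dropping a channel does not perturb the
rest.

Wide-field renderings mimic stitched low-magnification overviews: per
channel a maximum-intensity projection along z, Gaussian blur (default
10 µm), then block-mean downsampling (default 4×) with the pixel size
updated. Max projection — not sum — is used because that is how such
overviews are presented and measured.

What the generator does **not** emulate: irregular nodule margins,
parenchymal texture (airways, vessels), refractive-index artifacts, tile
seams, depth-dependent attenuation, and photobleaching. Passing tests
therefore demonstrate the correctness and statistical calibration of the
estimators under the stated imaging model, not robustness to every artifact
of real cleared-tissue data.

## Segmentation and counting

`segment_nodules` smooths the chosen channel with an isotropic physical
sigma (default 4 µm), applies a global threshold — Otsu by default, suited
to the bimodal tumor/parenchyma histogram; `median + k·MAD` for sparse
fields — optionally fills holes, labels connected components (26-
connectivity default), and discards components below `min_nodule_volume_mm3`
(default 2×10⁻⁵ mm³, roughly a 16-cell nascent nodule). Components touching
the field border are kept but flagged so profile analyses can exclude them.
A constant image yields an empty label map, not an exception.

`detect_cells` computes a negated Laplacian-of-Gaussian response at the
blob-matched scale sigma = r/√3 (anisotropic in voxels), keeps local maxima
above `median + k·MAD` of the response (k = 6; with 10⁷–10⁸ voxels per
field, 5-MAD exceedances occur by chance), suppresses maxima closer than
one cell radius keeping the stronger (ties broken by voxel order), and
refines positions by per-axis parabolic interpolation. On noiseless images
(MAD = 0) any clearly positive response qualifies.

Counting accuracy is resolution-limited: at 3 µm voxel pitch recall is
≥ 0.97 with precision ≈ 1 at SNR 10, while 5 µm survey-grade sampling
under-counts markedly because the LoG response of a 5 µm-radius punctum is
then barely above voxel noise. Quantitative density work in this package
therefore samples at ≤ 3.5 µm pitch, matching the practice of counting
cells on cellular-resolution acquisitions rather than overview scans. The
residual negative bias at the top of the density range (~5–8% at
60,000 mm⁻³) comes from genuinely unresolvable cell pairs whose responses
merge.

`segmentation_concordance` matches nodules across two label maps one-to-one
greedily by voxel overlap and reports the Spearman rank correlation of
matched volumes — the statistic used to argue that nuclear-stain and
reporter-based segmentation are interchangeable.

## Per-nodule quantification and calibration

Volumes are voxel counts × voxel volume (1 mm³ = 10⁹ µm³). Detections are
assigned to the nodule whose voxel contains them; detections on background
are tallied as peritumoral and excluded (strict containment), so
density × volume = count holds exactly in the output table.

"Integrated fluorescence density" of a wide-field image is defined here as
the background-subtracted (median outside all footprints, negatives
clipped) summed intensity per µm² of projected nodule footprint; per-area
normalization stops nodule size from trivially driving the signal.
`fit_calibration` fits counts against density through the origin by default
(a pure conversion factor; free intercept available) and reports the
Pearson r of the pairs. `infer_density_from_widefield` applies the model,
clipping negative extrapolations to zero with a warning. Because areal
density and total count only share scale when nodule sizes are comparable,
the image-level calibration experiment uses similar-sized nodules — the
same regime in which such conversions are used in practice.

## Core/rim profiles

`extract_profile` takes the central slab of z-slices (cross-sectional area
≥ 50% of the maximum — averaging several sections through the center is
far more stable for sparse punctate signal than any single optical
section), casts 36 evenly-spaced diameters through each slice's centroid,
samples each boundary-to-boundary chord at ¼-voxel steps, rescales it to
0–100% so tumors of all sizes are comparable, subtracts the off-nodule
median background (signed — per-pixel clipping would rectify noise into a
pedestal), and averages per-ray bin means into 10 equal bins. Each ray is
the independent unit: the profile also carries per-bin standard errors from
the ray-to-ray scatter.

`core_rim_ratio` = mean over 40–60% ÷ mean over (0–10% ∪ 90–100%). When the
profile carries uncertainties, a rim mean below its own standard error is
floored at that error, saturating the ratio at the profile's measurable
dynamic range; an unmeasurably small rim otherwise produces arbitrarily
large or infinite ratios that destroy downstream group statistics. Profiles
without uncertainties keep the raw contract: zero rim with nonzero core is
+inf (warned), both zero raises.

`compare_groups` is a two-tailed unpaired t-test, Student (pooled variance)
by default to match common practice in this literature; Welch is available
and preferable when group spreads differ visibly — the core/rim Monte Carlo
here is significant under either. Zero variance in both groups with equal
means returns p = 1 by convention; with unequal means the comparison is
degenerate and raises.

## Colocalization

Object level: one-to-one greedy nearest-neighbor matching in increasing
distance order, matches beyond the radius (default one cell radius, 5 µm)
rejected; the two directed fractions are matched/total per side. Greedy
matching is deterministic and near-optimal at biological cell densities.
Pixel level: Pearson or Spearman correlation over a caller-supplied mask —
use the nodule mask, since empty parenchyma inflates correlation. Voxel-
scale correlation of barely-resolved puncta is attenuated by independent
noise; the colocalization driver bins to 10 µm (cell-sized) superpixels
before correlating, which is what a ×10 overview image effectively
measures.

## Validation experiments and problem sizes

`lungtam.experiments` fixes the reference study conditions (all SNR 10
unless stated):

- **Volume recovery** — 10 nodules, radii 50–300 µm, contrast 5, 5 µm
  voxels in a 2×2×0.8 mm field; every nodule must be found with per-nodule
  volume error ≤ 15% and total-burden error ≤ 10% (measured: ≲ 0.1%).
- **Density recovery** — 16 nodules over two 1.4×1.4×0.7 mm fields at 3 µm
  voxels, densities log-uniform 8,000–60,000 mm⁻³; ≥ 95% of nodules within
  10% of truth.
- **Calibration** — 50 replicates of 30 (density, count) pairs with 20%
  multiplicative noise; Pearson r ≥ 0.9 in ≥ 90% of replicates and slope
  recovery within 10% at 5% noise.
- **Core/rim validity** — 50 replicates of n = 14 rim-biased vs n = 14
  core-biased single-nodule fields (radius 100 µm, density 30,000 mm⁻³,
  bias 2, 5 µm voxels): correct mean ordering in every replicate, t-test
  power ≥ 80%, and a uniform-vs-uniform null rejection rate ≤ 10% at
  α = 0.05.
- **Colocalization** — 250 cells, channel B an exact 80% subset of channel
  A at 2.5 µm voxels; directed fractions within ±0.05 of (0.80, 1.00).
- **Concordance** — nuclear vs reporter segmentation of one 8-nodule field
  at SNR 30; matched-volume Spearman ρ ≥ 0.95.
- **Determinism** — the full pipeline run twice on one config+seed must
  produce byte-identical CSV/JSON outputs (fixed column order, `%.8g`
  floats).

These sizes give stable statistics while each experiment completes in a few
minutes on a single CPU; `scripts/acceptance.py` re-runs all of them from a
seed and writes the measured quantities as JSON.

## Known limitations

- Ellipsoidal nodules and a flat parenchyma mean Otsu thresholding faces an
  easier histogram than real tissue; threshold-rule robustness to texture
  is untested.
- Counting degrades above ~5 µm voxel pitch and near cell-pair resolution
  limits; no split/merge post-processing is attempted.
- The wide-field calibration assumes comparable nodule sizes; across a wide
  size range, areal density and total count decouple by construction.
- Max-projection wide-field intensity saturates at high TAM density
  (overlapping puncta in projection), compressing the top of the
  calibration curve; rank statistics are unaffected.
- The core/rim ratio's SEM floor bounds, but does not remove, the heavy
  upper tail of ratios for strongly core-biased nodules; group comparisons
  on small n remain sensitive to it.
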