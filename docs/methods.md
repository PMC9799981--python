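# Methods

This note documents the model behind each analysis arm, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical choices that matter.

## Imaging: foci detection, counting, colocalization

**Model.** Nuclear RNA foci (paraspeckles marked by *Neat1* FISH, or single
mRNA molecules in smiFISH) are diffraction-limited, approximately Gaussian
spots on a slowly varying background. Detection enhances blobs with a
negated Laplacian-of-Gaussian (LoG) filter and takes strict local maxima of
the response above a threshold.

* **LoG scale `log_sigma`** (px, default 1.5): should match the PSF standard
  deviation; at 0.1 µm pixels this corresponds to a ~300 nm FWHM confocal
  PSF. The filter family is fixed; its scale is a user parameter because the
  acquisition optics vary.
* **Threshold**: an absolute LoG-response cutoff, or (default) a robust
  automatic value, median + 5 × 1.4826·MAD of the response image. Detected
  spot count is monotone non-increasing in the threshold.
* **Local maxima** use 8-connectivity in 2D and 26-connectivity in 3D;
  plateaus of exactly equal response yield one spot at the plateau centroid.
* **Nucleus segmentation** = Gaussian smoothing (σ = 2 px) → Otsu threshold
  → hole filling → removal of objects below `min_area` (default 50 px) →
  distance-transform watershed to split touching nuclei. A blank nuclear
  channel returns an empty mask with a warning. All steps are deterministic.
* **Per-cell statistics** include zero-focus nuclei in the denominator;
  spots outside every nucleus keep label 0 and are excluded from
  foci-per-cell means (cytoplasmic signal is reported separately, since the
  long *Neat1_2* isoform is seen in the cytoplasm).
* **3D stacks** are analyzed in 3D when voxel metadata (0.45 µm z-step) is
  present, otherwise maximum-intensity projected.
* **Colocalization** is greedy one-to-one nearest-neighbour matching in
  increasing distance order with a hard cutoff `max_dist` (default 0.3 µm,
  about one PSF width). Greedy matching is order-independent, symmetric in
  count, and equals the minimum-total-distance matching whenever candidate
  pairs are separated by more than the cutoff — the regime distance-based
  colocalization calling is meant for. Coordinates are 0-based pixel
  indices; voxel sizes convert to µm.

## AP-MS differential interactome

**Pipeline order is fixed and enforced** (each step checks the stage of its
input): unique-peptide summation → median normalization → 5 %-quantile
imputation → log2 → technical-replicate averaging → pooled-variance t-test →
confidence filters.

* Shared peptides (mapped to more than one protein) contribute to no protein
  and are dropped with a logged count.
* **Normalization** rescales each run multiplicatively so all run medians
  (over observed values) equal the median of the original run medians;
  missing entries are untouched. This corrects the log-normal run-level
  loading offsets the generator emulates.
* **Imputation** replaces missing values per run by that run's 5 % quantile
  of observed intensities, computed with linear interpolation between order
  statistics, on the linear (post-normalization, pre-log2) scale — matching
  the pipeline order above. Imputation is idempotent. The pre-imputation
  observation mask is carried forward for the confidence filters.
* **Test**: per protein and pairwise comparison (the four canonical
  condition × compartment contrasts), log2FC = mean(group1) − mean(group2)
  on log2, technically averaged data, and an unpaired two-tailed Student
  t-test with pooled (equal) variance — deliberately not Welch. *Enriched* ⇔
  |log2FC| > 1 (fold change > 2 or < 0.5) and p < 0.05. Zero-variance
  degenerate cases: identical groups give t = 0, p = 1; zero pooled variance
  with a non-zero difference gives p floored at 1e−300 (the same cap maps
  p = 0 in volcano coordinates, with a warning).
* **Confidence filters** (to remove false positives from low-intensity
  quantitation): total averaged PSM count strictly > 4, and quantified
  before imputation in at least 2 biological replicates of at least one
  compared group. No multiple-testing correction gates the flags; a
  Benjamini–Hochberg column (`p_bh`) is emitted for reference only.
* **Volcano** coordinates are (log2FC, −log10 p) with guides at |log2FC| = 1
  and −log10 p = −log10(0.05) ≈ 1.30.
* **Paraspeckle overlap**: the packaged 40-component annotation (name,
  alternative name, structural class, ITAF function, interactome presence)
  is matched case-insensitively with alternative names honoured. Note one
  documented inconsistency in the source material: hnRNPR is described as an
  ITAF-functional interactome member in prose but its tabulated presence is
  "No"; the packaged table follows the tabulated value, so the 22/40 overlap
  contains 6 ITAF-functional components (p54^nrb^ itself among them).

**Known limitation.** Quantile imputation is left-censoring-aware but
biased: for proteins whose baseline abundance sits below the detection
limit, imputed values exceed the (unobservable) truth and shrink estimated
fold changes toward zero. The estimator is unbiased when measurements are
observed; spike-recovery remains ≥ 90 % under the default censoring model
because strongly enriched interactors are well observed in at least the
enriched group.

## Polysome PCR array (2^−ΔΔCT)

Technical replicates are averaged in Ct space (standard qPCR practice).
ΔCt = Ct(gene) − Ct(reference, default Gapdh) within each sample cancels
per-sample additive shifts exactly. ΔΔCt subtracts the mean calibrator ΔCt
(default: control gapmer), and RQ = 2^−ΔΔCt; averaging ΔΔCt across
biological replicates in log space keeps the calibrator's RQ exactly 1.
Undetermined Ct values are treated as missing, never as Ct 40; a gene with
no usable replicates in a cell is flagged not-quantified and excluded from
summaries with a logged count.

* **Recruitment metric**: default `polysomal_over_total` (RQ in the
  polysomal fraction divided by RQ in total cytoplasmic RNA, the
  translational-efficiency proxy); `polysomal_only` is also provided because
  the normalization chain (reference gene + calibrator) is defined per
  fraction. The metric used is recorded in the output.
* **Signed fold change**: RQ if RQ ≥ 1 else −1/RQ, so |FC| ≥ 1 and
  f(RQ) = −f(1/RQ). A repressed gene at RQ 0.5 reports −2.
* **Class summaries** (IRES / ITAF / other): percent decreased (RQ < 1),
  increased (RQ > 1), unchanged (RQ = 1), reported as exact fractions plus
  integer-rounded percents. No dead band by default; an optional one exists.
  ΔΔCt values within 1e−9 of 0 (and recruitment ratios within 1e−9 of 1) are
  snapped to the unchanged category so floating-point jitter cannot move a
  truly unaffected gene across the RQ = 1 boundary.

## Dual-luciferase reporter

Background per channel = plate mean of non-transduced wells, subtracted from
every reading; wells at or below background are invalidated rather than
clamped (a clamped LucR would make the ratio meaningless). IRES activity =
LucF/LucR per well; the biological replicate value is the mean of its
technical ratios (typically 3); normalization divides by the reference-group
mean (so the reference mean is exactly 1). Mean-division rather than
matched-pair division was chosen because replicate pairing across groups is
generally not defined on these plates.

Mann-Whitney U is exact (full enumeration of the permutation null) whenever
n1 + n2 ≤ 20 without ties — which covers the n = 9 per group design —
otherwise the normal approximation with tie correction is used; completely
tied samples return p = 1. The method used is recorded in the output.

## Synthetic-data generators

All generators are deterministic given their config's single `seed`.

* **Images**: disk-shaped nuclei (radius 18 px default) placed without
  overlap; per-cell spot counts Poisson (rate 2.0 per channel default);
  isotropic Gaussian spots (σ 1.5 px, amplitude 100) on constant background
  (10) with Gaussian read noise (sd 2); optional colocalized Cy5 spots
  placed within a small offset of Cy3 spots; optional minimum intra-nucleus
  spot spacing for detection benchmarks. Not emulated: realistic PSF shape
  or z-anisotropy, uneven illumination, autofluorescence, nuclear texture —
  so passing detection benchmarks bounds algorithmic, not acquisition,
  error.
* **LFQ**: protein log2 intensities ~ N(22, 2.5); groups = condition ×
  compartment; 3 biological (4 in the benchmark configs) × 2 technical
  replicates; biological sd 0.3 (log2), technical sd 0.1, run-level offsets
  sd 0.2; left-censored missingness, logistic in log2 intensity (midpoint
  18, scale 1, max rate 0.9 — overall ≈ 5–10 % missing); spiked proteins
  shift group1 of their stated comparison only; PSM counts Poisson with an
  intensity-linked rate, 0 where the protein is unobserved; two peptides per
  protein whose intensities sum exactly to the protein's. Not emulated:
  peptide-level variance structure, shared-peptide ambiguity rates,
  cross-run identification transfer.
* **Ct tables**: gene baselines uniform in [22, 30] cycles (reference in
  [18, 20]); per-sample additive offsets (sd 0.5) emulate plate shifts and
  must cancel in ΔCt; configured recruitment effects lower the polysomal-
  fraction Ct by the effect in cycles so the noise-free table inverts
  exactly through 2^−ΔΔCT; technical noise Gaussian in Ct; values clipped to
  [5, 40]. Two biological × three technical replicates by default, matching
  the array design.
* **Plates**: per-biological-replicate log-normal scale (cell number) shared
  by both channels, independent per-channel measurement gains with CV 10 %,
  additive background (mean 500 RLU); defaults encode a 2× hypoxic
  activation of the FGF1 reporter (0.2 → 0.4) and a hairpin control two
  orders of magnitude lower, nine biological × three technical replicates.

## Benchmark problem sizes

The acceptance script and tests use: 50 fields of 300 × 300 px with 10
nuclei each (500 cells) at spot SNR 5 and ≥ 4σ spacing for detection F1 and
foci-rate recovery; a 2000-protein no-spike simulation for type-I error
(99 % binomial interval around 0.05); 20 seeds × 20 spiked proteins
(|log2FC| = 2, biological sd 0.3, 4 vs 4) for recovery; zero-noise Ct and
plate simulations for machine-precision round trips. These sizes give
Monte-Carlo error comfortably inside each tolerance while keeping a full run
in tens of seconds.
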