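# Methods

## Image model and conventions

Volumes are 3-D scalar arrays ordered `(slice, row, col)` with slices
along the cranio-caudal axis, voxel spacing `(dz, dy, dx)` in mm and a
physical origin at the centre of voxel (0, 0, 0). Indices are 0-based and
all slice ranges are half-open `[start, stop)`. NIfTI volumes are
reoriented to closest-canonical (RAS) on load so the slice-based
algorithm always sees a consistent axial stack; DICOM series are read
with per-slice rescale slope/intercept applied and are rejected on mixed
series UIDs or inconsistent slice spacing. Negative PET concentrations
(reconstruction artifacts) are clamped to zero with a logged count.
Concentrations are assumed scanner-decay-corrected, as is standard for
clinical DICOM PET, so SUV is simply `C · weight / dose`.

## Psoas segmentation

The operator supplies the slice range (soma of D12 to the L5–S1 plane)
and one seed point inside each muscle on the first slice; these stand in
for the visual-inspection step of the clinical procedure and make runs
reproducible without an operator.

Per slice:

1. **Equalization.** HU values are clipped to a body window (default
   −200…300 HU, covering fat through muscle and saturating bone and air)
   and globally histogram-equalized to [0, 1]. Equalization is a rank
   transform, so the segmentation is invariant to constant HU shifts that
   keep tissue inside the window.
2. **Edge detection.** A Canny detector (σ = 2 px) with hysteresis
   thresholds expressed as fractions (0.10 / 0.30) of the slice's maximum
   smoothed-Sobel gradient magnitude. Relative thresholds are the
   default because equalization maps plateau contrast to histogram mass:
   the same anatomical boundary produces gradients two orders of
   magnitude apart on noise-free versus noisy slices, and
   gradient-quantile thresholds drift when large organs enter the field.
   Absolute thresholds remain available (`canny_relative_thresholds=False`).
3. **Contour closure.** Edge pixels within `search_radius_px` (default
   45) of the tracked point are considered. If the 8-connected edge
   chain already encloses the point, the enclosed free space is
   flood-filled and its boundary taken directly, shrunk by half a pixel
   so it passes through the edge-pixel centres (the gradient ridge). The
   slightly interior boundary is deliberate: it keeps boundary-straddling
   pixels — partial-volume mixtures of muscle and surrounding fat — out
   of the attenuation and uptake statistics, at the price of a small
   (order −5 %) volume bias at clinical resolution. If the chain is
   open, an α-shape closes it: triangles of the Delaunay triangulation
   are kept while their circumradius is at most the α-disc radius, and
   the closed boundary rings of the union (outer boundaries and holes)
   become candidate regions. By default the radius is auto-tuned per
   slice and side to the smallest value that closes a contour around the
   tracked point; a fixed `alpha` (1/radius) may be configured instead.
4. **Selection and tracking.** Among candidates containing the tracked
   point whose area is within `area_ratio_bounds` (default 0.5–2.0) of
   the previous slice's region, the smallest (innermost) is selected —
   the inner-muscle region rather than any surrounding ring. Its
   centroid becomes the next slice's tracking point.

Sides that fail on a slice are repaired by copying the nearest selected
polygon of the same side, up to `k_missing = 2` consecutive slices;
longer runs abort with an error naming the slices. Polygons are
rasterized by the pixel-centre-inside (even-odd) rule into a mask with
labels 1 (left of the image midline) and 2 (right).

## ROI metrics

Volume is voxel count × voxel volume; AAC is the arithmetic mean HU over
both sides pooled, computed on the CT-grid mask. For the metabolic
indices the mask is resampled to the PET grid by *exact box overlap*: the
covered volume fraction of each PET voxel is a separable product of
per-axis interval overlaps, so the computation is exact rather than a
nearest-neighbour approximation and conserves volume to within the
surface-voxel layer. A PET voxel enters the mask when its total covered
fraction reaches `frac_threshold` (default 0.5) and takes the side label
with the larger share (ties, which require exactly equal coverage, go to
the left label). PET values under the mask are used as-is, without
interpolation.

VC-SUV uses the sample (n−1) standard deviation — immaterial at the
voxel counts involved but fixed for determinism. It is mathematically
invariant to the liver normalization; the liver mean (from a supplied
mask or a 30-mm sphere at a configured centre) still validates the
N-SUV denominator. The myocardial variant enforces the 10 mL minimum
VOI; the source procedure also quotes an average VOI of 6 ± 3 mL, which
contradicts that minimum — the explicit minimum is enforced and the
conflict noted here.

The Robinson ideal-body-weight formula (52/49 kg base at 60 inches plus
1.9/1.7 kg per inch for men/women) floors at the base weight for shorter
subjects; volume is reported both raw (mL) and per kg IBW.

## Survival analysis

Stratification splits at the median (midpoint of central order
statistics for even n); ties go to the low group, so "low" means ≤
median. Mortality rates are reported as whole percents, nearest integer
with exact halves rounded *down* (21/56 → 37 %), matching the convention
of the clinical tables this layout reproduces. Kaplan–Meier estimation
and the log-rank test are delegated to lifelines; Cox models use
statsmodels PHReg with Breslow tie handling, Wald 95 % intervals and
p-values. Backward elimination drops, at each step, the variable whose
likelihood-ratio-test p (against the current model) is largest, while it
exceeds `removal_p = 0.1`; an empty final model is a legitimate outcome,
and one-group-without-events separations are returned flagged rather
than as silent failures. Significance is two-sided 0.05 throughout with
no multiplicity correction; a Schoenfeld-residual hook is exposed for
proportionality diagnostics but not used by the pipeline. Whether the
univariate models should use the continuous variable rather than the
split indicator is genuinely open; the split indicator is the default
(matching the two-group table layout) and `split=False` exposes the
continuous option.

## Synthetic data

The phantom emulates what the pipeline needs from abdominal PET/CT and
nothing more: two psoas-like elliptic cylinders (semi-axes 28 × 20 mm,
linearly tapered to 80 % at the ends of a 32-slice range) flanking a
high-attenuation vertebral block, plus a liver ellipsoid as SUV
reference, on a 256 × 256 × 40 CT grid at 1 × 1 × 3 mm and a
64 × 64 × 40 PET grid at 4 × 4 × 3 mm, the PET grid offset in-plane by
1.5 mm to exercise the box-overlap resampler. Defaults encode the
disease-cohort magnitudes (muscle 39.4 HU; liver SUV 2.0; muscle SUV
0.90, i.e. N-SUV 0.45, with 8 % voxel-wise CV; body weight 69 kg, dose
345 MBq = 5 MBq/kg). Noise is Gaussian in the image domain (defaults
5 HU CT, 0.02 SUV PET): the package tests image-domain analysis, not
reconstruction, so Poisson projection noise, scatter and PSF modelling
are out of scope. Hard tissue boundaries make the phantom *harsher* than
real data for boundary-sensitive statistics, but its lack of
partial-volume gradation, anatomical texture and neighbouring soft-tissue
structures means passing tests bound algorithmic correctness, not
clinical segmentation accuracy.

The cohort simulator draws the seven prognostic covariates as
independent Gaussians with disease-cohort means/SDs (age 62 ± 12,
ALSFRS-R 39 ± 5, cervical-cord N-SUV 0.96 ± 0.30, psoas volume
3.6 ± 1.02 mL/kg, psoas N-SUV 0.45 ± 0.19, VC-SUV 8 ± 4 %, motor-cortex
SUV 5.59 ± 1.30), floored at physiological minima. Survival times are
exponential with hazard `λ₀ · exp(Σ βᵥ zᵥ)` on standardized covariates
(βᵥ = per-SD log hazard ratio); censoring is independent
Uniform(0, 60 months). λ₀ = 0.017/month makes ~37 % of null-model
subjects die before censoring, matching the observed death fraction.
Real cohorts have correlated covariates and non-exponential hazards;
the simulator tests estimator calibration, not clinical effect sizes.

## Problem sizes and numerical choices

Phantom recovery runs at the full 256 × 256 × 40 / 64 × 64 × 40
resolution (seconds per volume). Simulation studies use 200 replicates
of two-arm n = 500 cohorts for CI coverage and 100 replicates of n = 500
seven-covariate cohorts for backward elimination — large enough that
binomial noise on a 90–95 % rate is ~2–3 points. Oracle equivalences are
checked exhaustively on instances of ≤ 8 subjects (log-rank), 60-subject
tied-time samples (KM vs ECDF) and 10³-voxel grids (downsampling).
Coverage-fraction comparisons use a 1e-12 absolute tolerance; the mask
inclusion threshold is applied with a 1e-12 slack so exact 50 % coverage
is included. The α-radius auto-tune binary-searches the sorted
circumradius levels, so results are deterministic; degenerate inputs
(constant slices, collinear edge points, empty masks, zero-event groups)
raise typed errors rather than propagating NaNs.

## Known limitations

* The segmentation assumes one connected region per side per slice and
  breaks (by design, with an error) when more than `k_missing`
  consecutive slices fail on a side.
* The half-pixel interior bias underestimates volume by ~5–7 % at
  clinical resolution, more for very small muscles; Dice against ground
  truth remains ≥ 0.95 at clinical scale.
* Backward elimination with `removal_p = 0.1` retains each null
  covariate with ~10 % probability, so with six null covariates the
  final model is the signal variable alone only ~53 % of the time —
  an inherent property of stepwise selection at that threshold, not an
  implementation artifact (the signal variable itself is retained in
  ~100 % of replicates).
* Vertebra identification, spinal-cord and brain ROI extraction are out
  of scope: cord and motor-cortex uptake enter the survival analysis as
  supplied cohort-table columns or precomputed ROI means.
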