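# Methods notes

This note records the models behind each pipeline stage, the parameters
that matter, what the synthetic phantoms do and do not emulate, and the
numerical choices made where the procedure left room for interpretation.
No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` compute.

## CT body composition

### Procedure

1. **Hounsfield normalisation** — affine rescale `slope·raw + intercept`;
   a zero slope is an invalid calibration.
2. **Body mask** — Gaussian blur with a *physical* σ of 0.1 mm (converted
   per axis to voxels via the header spacing), threshold ≥ −700 HU,
   largest connected component, holes filled. Hole filling matters: lung
   air (≈ −900 HU) falls below the body threshold, and the denominator of
   the fat fraction is "whole body volume excluding air", which presumes
   the body solid includes its cavities.
3. **Candidate fat** — voxels inside the body with −250 ≤ HU ≤ 50
   (closed interval; "between" read inclusively, a measure-zero choice on
   continuous data). Fat and air thresholds are applied to the *original*
   normalised volume. The blur exists to stabilise the body threshold; at
   typical phantom spacing (0.2 mm) it is only 0.5 voxel wide, and
   thresholding the blurred volume would systematically bleed roughly one
   voxel of every fat/tissue interface into the fat window (soft tissue at
   60 HU crosses the 50 HU bound at ~1.5 σ of the blur profile), a bias of
   order +10 percentage points on shell-like fat geometry. Sharp-volume
   thresholding has no such bias.
4. **Partial-volume correction** — air is everything < −250 HU after
   removing connected objects smaller than `min_object_voxels` (default
   27 = 3³, one structuring-element volume). The air mask is grown by a
   3-iteration binary dilation with the 6-connected cross (3 "pixels", in
   voxel units regardless of anisotropy, since the original description is
   in pixels); the lung — the largest air component strictly interior to
   the body, ties broken by lowest centroid (z, then y, x) — receives 3
   further iterations (6 total). Candidate fat under the grown air is
   discarded. Dilation is 3-D by default with a per-slice 2-D option.
5. **Cleanup** — remaining fat components smaller than
   `min_object_voxels` are removed and fully enclosed cavities are filled
   in 3-D; filled voxels are never allowed back inside the dilated-air
   exclusion zone.
6. **Fat fraction** — `100 · |fat| / |body ∖ air|`, plus the voxel volume
   in mm³ for absolute masses.

Connected components use **face (6-)connectivity** for objects and for
hole filling. This is the default of ITK's connected-component machinery,
on which this family of pipelines is historically built, and it is also
the only choice under which speckle removal can work at realistic noise:
with 26-connectivity the site-percolation threshold drops to ≈ 0.097
occupancy, which noise-misclassified voxels exceed at even moderate noise,
fusing them into one giant un-removable component.

### Accuracy envelope (measured, not assumed)

The phantom places soft tissue at N(60, σ) HU against a fat window ending
at 50 HU — a 10 HU margin. A tissue voxel is misclassified as fat with
probability Φ(−10/σ): 2% at σ = 5, 16% at σ = 10, 31% at σ = 20.
Small-object removal deletes isolated misclassifications but cannot touch
voxels that adjoin the true fat surface or that percolate into large
clusters (6-connected site-percolation threshold ≈ 0.31). Measured
recovery of the full pipeline: exact at σ = 0, within ~1.3 points at
σ ≤ 10, ~2 points around σ = 12, then +4 to +18 points for σ = 15–30.
This is an information limit of the 10 HU contrast margin, not a defect a
different morphological recipe could remove; real scans with soft tissue
further from the window edge (or finer voxels, where the 0.1 mm blur
spans several voxels) behave better than this phantom. The acceptance
report therefore carries both the full-envelope error (σ ∈ [5, 30]) and
the low-noise (σ ≤ 10) error.

The partial-volume property is unconditional: on phantoms with blurred
air/tissue interfaces and lung cavities, disabling the dilation exclusion
only ever adds interface voxels to the fat mask (in the extreme, the
in-window body-surface shell is closed and cavity filling floods the whole
interior), so the corrected run is strictly closer to truth on every
phantom tested.

## Adipocyte morphometry

Luminance uses the Rec. 709 weights; the linear stretch maps the 1st–99th
percentiles to [0, 255] (configurable; degenerate constant fields pass
through with a warning). The white threshold defaults to Otsu's method on
the stretched image with a fixed-value override. Components are
8-connected; the minimum cell area defaults to 200 µm² (below any
plausible adipocyte cross-section at 10–20× magnification, suppressing
inter-cellular white speckle), and border-touching components are excluded
by default. No watershed splitting is applied — the base procedure is
thresholding and detection only — but the area floor and threshold are
exposed for tissues where touching lumina merge.

Size distributions use half-open bins [e_i, e_{i+1}) with the final bin
closed; out-of-range cells go to a reported overflow count, and both raw
counts and proportions are emitted because published frequency plots are
ambiguous between the two.

## Stain %-area

The colour rules are explicit HSV predicates, since the original
operation ("a threshold for red") is colorimetrically under-specified:
picrosirius red = hue within ±20° of 0°, saturation ≥ 0.3, value ≥ 0.2;
DAB brown = hue 10–45°, saturation ≥ 0.25, value ≥ 0.15. Both are plain
dataclasses a user can replace wholesale. ROIs come in as polygon
vertices or full-field defaults; hand-drawn ROIs from the original
workflow are not reproducible and are out of scope.

## PET brown-fat activity

Shape-based interpolation was chosen over mesh morphing because it is
deterministic and standard: per-slice signed distance maps (positive
outside, negative inside, from Euclidean distance transforms) are linearly
interpolated along the slice axis and thresholded at ≤ 0. Input slices are
reproduced exactly from their rasterized polygons (even-odd fill);
polygons are validated as simple via their geometric validity. Interpolating
between concentric circles yields the analytically expected intermediate
radii to within a pixel; tracing an ellipsoid every 3 slices reconstructs
it with Jaccard ≥ 0.95.

%ID/g assumes unit tissue density (1 g/mL), the small-animal convention,
so ROI mass equals ROI volume; density is a parameter. Radioactive decay
correction for ¹⁸F (t½ = 109.77 min) is available but **off** by default
so the arithmetic matches the uncorrected convention; enabling it is an
explicit flag. PET-to-CT registration is assumed done upstream. The
agreement analysis regresses γ-count %ID/g on PET %ID/g (ordinary least
squares, Pearson r, two-sided slope p), one pair per animal.

## Indirect calorimetry

Diurnal membership is the half-open clock interval [lights_on,
lights_off); wrap-around schedules (lights on overnight) are supported;
equal on/off times are rejected. Energy expenditure defaults to the
Lusk-type thermal equivalents `EE = 3.815·VO₂ + 1.232·VCO₂` with VO₂ and
VCO₂ in L/h, the equation family CLAMS-class analysis software implements;
the abbreviated Weir form (3.941/1.106) is a named alternative and every
summary row records which formula produced it. Mass-specific inputs
(mL/kg/h) are converted using the recorded body mass; absolute inputs are
declared via an explicit units field, never guessed. The first 24 h of a
recording can be dropped as chamber acclimatisation.

## Expression quantification

The comparative-Ct implementation is ΔΔCt in substance: per sample
ΔCt = Ct(target) − Ct(reference, default 18s); the baseline is the
*arithmetic mean* of the control group's ΔCt (an explicit choice — a
single-calibrator convention is equally defensible but less stable); and
fold = 2^−(ΔCt − baseline). This makes the geometric mean of control
fold changes exactly 1. cDNA dilution factors are treated as pre-analytic
and not corrected in Ct space. The interval helper converts a Welch-t
interval on the ΔΔCt difference to an asymmetric interval on the fold
scale. Densitometry is the per-lane ratio to the loading control
(default β-actin), with an optional rescale so the control group's mean
is 1; zero-control lanes are dropped with a warning.

## Synthetic phantoms — what they emulate, and what they don't

All generators are pure functions of their parameters and seeds, record
their ground truth at generation time, and split geometry randomness from
noise randomness so that two phantoms can share exact truth masks while
differing in noise.

- **CT** (default 128×96×96 at 0.2 mm isotropic — a mouse-scale field of
  view that runs in seconds): soft-tissue ellipsoid body (60 HU) in
  −1000 HU air, two −900 HU lung lobes joined by an airway bridge (so "the
  largest air region inside the body" is the whole lung), and fat
  (−100 HU) grown from five compact depot sites until the requested
  fraction of |body ∖ lung| is hit exactly (the depot-distance field is
  thresholded at the order statistic matching the target voxel count).
  A 5-voxel soft-tissue rind under the skin and an 8-voxel clearance
  around the lungs mirror real anatomy (skin, mediastinum) and mean the
  3/6-voxel exclusion dilations never overlap true fat. Noise is additive
  Gaussian (default σ = 20 HU); an optional 1-voxel Gaussian interface
  blur emulates scanner partial volume. Not emulated: anatomical atlases,
  bone, beds with contact, scanner physics (beam hardening, rings).
- **Adipocyte mosaics**: space-filling polygonal cells from a weighted
  (power/Laguerre) tessellation on a periodic field — periodicity means no
  cell is clipped by the frame and lumen areas + membrane pixels exactly
  partition the field. Target lumen areas are lognormal with the requested
  mean; a second tessellation pass recalibrates polygon targets from the
  measured membrane loss so the realised lumen means track the request
  (the remaining deviation is the lognormal sampling error itself). Bright
  lumina (230) with dark membranes (60) and mild Gaussian noise. Not
  emulated: nuclei, crown-like structures, staining gradients, genuinely
  touching lumina with broken membranes.
- **Stained fields**: a Gaussian-smoothed random field thresholded at the
  order statistic that yields *exactly* the requested stained pixel count,
  giving organic blobs with exact truth; reference colours with small
  jitter. Not emulated: stain co-localisation, illumination fields.
- **PET**: hot ellipsoid of known concentration in a warm background,
  Gaussian (or Poisson) noise; contours traced from the true ellipse
  every 3 slices, as a human contourer spacing. Truth %ID/g comes from
  the noiseless concentrations.
- **Respirometry**: phase-constant VO₂ plus a sinusoid completing whole
  cycles inside each 12 h phase, so zero-noise phase means equal the
  constants exactly; VCO₂ is the phase RER times VO₂ pointwise; Poisson
  activity counts; cumulative food.
- **Tables**: Ct tables constructed so each gene's fold change is exact by
  construction (per-sample jitter moves reference and target together and
  cancels); densitometry tables with lane-loading jitter that cancels in
  the ratio.

Because the phantoms are geometrically clean, passing tests demonstrate
the *correctness of the quantification arithmetic and morphology* under
known contrast and noise — not robustness to real-tissue heterogeneity,
staining variability or scanner artefacts.

## Study orchestration and problem sizes

`run_study` executes the requested stages over a two-group synthetic
cohort, derives every per-subject seed from the root seed with stable
hashing, writes per-stage tidy CSVs with fixed numeric formatting (so
reruns are byte-identical), and reports group means ± SEM; inferential
statistics are deliberately left to standard tools on the per-subject
tables. Default validation sizes — 20 CT phantoms (128×96×96), 20 mosaics
(100–500 cells), a 9-subject PET cohort, 200 qPCR replicates, and a
3-per-group full study for the determinism check — were chosen so the
entire validation runs in a few minutes on one CPU while keeping each
population large enough to exercise the stated tolerance.
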