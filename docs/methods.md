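# Methods

`fidburn` re-implements, as a tested pipeline on synthetic data, the
accuracy analysis of an MR-only prostate radiotherapy workflow in which
gold fiducial markers (FMs) — invisible on a five-material synthetic CT
(sCT) — are "burned in" semi-automatically from their signal voids on the
water-Dixon MR image. Three questions are addressed: how reproducible is
the burn-in across observers, how accurate is marker-based position
verification against the conventional CT-based workflow, and how do
inter-observer registration errors compare between workflows.

## The burn-in procedure

An observer delineates each marker's signal void on three consecutive
slices of the water-Dixon image (in-plane 1.7 × 1.7 mm, slices 2.5 mm).
The delineation is expanded isotropically by a physical margin
(default 2 mm), the `k` lowest-intensity voxels inside the expanded
region are selected (default `k = 6`), their unweighted center of mass
(COM) is the marker position, and the selected voxels are written into
the sCT at 3000 HU.

Numerical conventions, all recorded per run in `run_log.json`:

* **Expansion** is in 3D physical space ("isotropic" in mm, not voxels):
  a voxel joins the expanded region iff its center lies within the margin
  of some input-voxel center. On the default grid a 2 mm margin adds only
  the four in-plane neighbours (in-plane diagonals are 2.40 mm away,
  adjacent slices 2.5 mm).
* **Tie-break** on equal intensities: ascending raster order, CC-major,
  then AP, then RL. Selection is therefore deterministic across runs and
  platforms.
* **COM** is the unweighted mean of the selected voxel centers, not
  intensity-weighted.
* **Burn-in** replaces (not blends) the voxel value with the burn HU.
  A voxel claimed by two overlapping marker selections is burned once and
  counted in the run log.

Inter-observer COM variability is the per-marker sample SD (n−1) of the
RL, CC and AP components across observers, summarized as the fraction of
markers below scatter thresholds. Unlabelled COMs (e.g. misidentified
structures) are clustered by greedy nearest-COM matching within a 5 mm
gate before the SD is computed.

## Rigid geometry

Registrations are 6-DOF transforms: translations along RL, CC, AP (mm)
and rotations about those axes (degrees). The angle convention —
*extrinsic* rotations about the fixed RL, CC, AP axes applied in that
order, rotation center at the moving-point centroid — is a genuine
choice: reported rotation parameters depend on it, and clinical
registration software rarely documents its own. It is fixed here, stated
in every serialized transform, and only matters beyond round-off for the
degree-scale angles in play.

`fit_rigid` is the closed-form least-squares (Kabsch) solution via SVD of
the cross-covariance of the centered point sets, with the determinant
constrained to +1 (no reflection, no scaling). It is exact to 1e-9 on
noiseless data for any non-collinear configuration of ≥ 3 markers.
Composition and inversion go through homogeneous matrices with parameter
re-extraction; extraction raises on the gimbal-degenerate case
(|rotation about CC| → 90°), far outside the clinical range.

Position-verification correction: an sCT-CBCT registration is expressed
in the CT frame by composing it with the marker-based CT-sCT fit
(`compose(ct_sct, sct_cbct)`, i.e. the CT-sCT map applied after the
sCT-CBCT registration). The alternative composition order would be
`compose(sct_cbct, ct_sct)`; with the transforms at clinical magnitude
the two differ at second order in the angles, and the chosen order is the
one under which the synthetic round trip (markers moved by a known
CT-sCT transform) reproduces the true CT-CBCT parameters exactly, which
the test suite verifies to 1e-9.

Registration quality is the per-axis RMS of the marker COM difference
vectors remaining after the fit.

## Error statistics

For a cohort with several registrations per patient, each parameter is
decomposed as: population mean `M` = mean of per-patient means,
systematic error `Σ` = SD (n−1) of per-patient means, random error
`σ` = RMS of per-patient SDs — the decomposition used by margin recipes.
Two alternatives were considered and rejected: a plain mean of
per-patient SDs for `σ` (differs by < 3% at these spreads), and a bias
correction for `Σ`. On the latter: the SD of patient means estimates
`sqrt(Σ² + σ²/m)` for `m` registrations per patient, because the
per-fraction noise inflates the patient means. No correction is applied
— the convention reports the uncorrected SD — but the consistency tests
compare the estimator against its actual estimand (at 24 fractions per
patient and these magnitudes the inflation is ≈ 3%). Patients with a
single record keep their contribution to `M` and `Σ` but are excluded
from `σ` and counted.

Inter-observer error uses two summaries: per patient, the IQR across
observers (quantiles by linear interpolation, the "type 7" rule; SPSS's
default differs slightly, so the rule is stated and pinned by tests);
pooled, the SD after subtracting each patient's mean — exactly invariant
to arbitrary per-patient offsets.

Hypothesis tests, significance fixed at 5% with no multiplicity
correction (each parameter is reported, not screened):

* **Paired Wilcoxon signed-rank**, two-sided. Zero differences are
  dropped (Wilcoxon's original method, matching common SPSS behaviour);
  tied absolute differences get midranks. For n ≤ 15 the null
  distribution of W⁺ is exact, built by convolution over the doubled
  midranks (doubling makes .5-midranks integral, so ties are handled
  exactly); beyond that a normal approximation with tie-corrected
  variance and a 0.5 continuity correction is used. The implementation
  is authored here because standard exact routines decline tied data;
  tests check it against full sign-vector enumeration (to 1e-12) and
  against the reference approximation on tie-free data.
* **Non-parametric Levene** for equality of spread: the Brown–Forsythe
  variant, a one-way ANOVA on absolute deviations from each group's
  median. A rank-transformed variant is available behind a flag since
  the name "non-parametric Levene" is not unique in the literature.
  Degenerate inputs (all deviations equal) return p = 1 with a flag.

## The synthetic phantom

The phantom emulates what the analyses need and nothing more: a body
ellipse of water-rich tissue with a fat shell, two compact/spongy bone
spheres, air outside — five materials, mapped to arbitrary HU defaults
(air −1000, fat −100, water-rich 30, spongy 200, compact 700; the
classes matter, the values do not enter any analysis). Markers are
1 × 5 mm cylinders placed ≥ 10 mm apart in a central prostate-like
region, oriented within 30° of CC (clinical implantation is roughly
cranio-caudal). Rasterization supersamples each voxel 3× per axis and
averages cylinder occupancy — at 1.7 × 1.7 × 2.5 mm a 1 mm cylinder is
sub-voxel and naive rasterization would drop it. The MR void multiplies
the local intensity by `1 − void_contrast · occupancy`
(default contrast 0.6).

Because the void's size on the water-Dixon image is not a
well-characterized quantity, the void is dilated beyond the physical
marker by a configurable factor (default 2: a ≈ 2 × 6 mm void for a
1 × 5 mm marker), standing in for the susceptibility "blooming" around
gold.
Without it the 1 mm cylinder intersects only ~3 voxels and a k = 6
selection would be padded with background ties, which is neither what
real images show nor a property of the method under study.

Observer delineations are three-slice discs (in-plane radius 2.5 mm)
centered on the marker after Gaussian jitter (default SD 0.5 mm, a
plausible manual-pointing scatter well below the voxel size); with a
configurable probability the delineation is instead placed on a spurious
void-like location ≥ 6 mm from every marker, emulating a misidentified
marker or calcification. Optional calcification confounders are ~2 mm
spherical voids on MR absent from the truth table and the sCT.

Registration cohorts come from the generative inverse of the error
decomposition: per patient one systematic offset
~ N(population mean, Σ²), per fraction additive N(0, σ²) noise,
independent per parameter. Noise is additive Gaussian, not Rician: the
burn-in analyses depend only on the intensity rank ordering near voids,
and the cohort statistics never touch image intensities.

All randomness flows from explicit seeds through `SeedSequence` children
spawned in a fixed documented order (placement, calcifications, noise);
phantoms are bit-identical for a fixed config.

**What passing tests do and do not show.** The phantom has perfect
five-material segmentation, no intensity inhomogeneity, no geometric
distortion, no prostate deformation between scans, and voids with a
known, uniform contrast. Results on it validate the *procedure* —
selection determinism, COM accounting, transform algebra, estimator
correctness — not the clinical difficulty of recognizing voids on real
images, which is exactly the part the method leaves to a human observer.

## Problem sizes and defaults

| quantity | default | note |
|---|---|---|
| grid | 64 × 64 × 48 @ 1.7 × 1.7 × 2.5 mm | Dixon acquisition grid; extent ~109 × 109 × 120 mm |
| markers | 4 | 1 × 5 mm gold cylinders |
| expansion margin | 2 mm | physical, anisotropic-aware |
| k | 6 (range 1–15) | protocol choice under study |
| burn HU | 3000 | replaces prior value |
| observers | 7 | inter-observer studies |
| IOE cohort | 20 patients × 7 observers | per workflow |
| position-verification cohort | 26 patients × 24 fractions | RL generators M −0.2, Σ 2.8, σ 3.3 mm |

The analysis drivers use 20 phantoms × 4 markers (80 markers) for the
COM-variability sweep; estimator-consistency tests run one cohort of
2000 × 50. These sizes give standard errors small enough for 3-SE
recovery checks while keeping any single script in the seconds range.

## Known limitations

* No intensity-based or chamfer image registration: CBCT matching is
  represented at the marker/transform level, so CBCT image artifacts are
  out of scope by construction.
* Marker correspondence across modalities assumes labels or unambiguous
  geometry; two markers within 2 mm raise an error rather than guess.
* The phantom's void model is a contrast-scaled occupancy, not MR
  physics; `void_contrast` and the dilation factor are free parameters,
  and conclusions that depend on their exact values (e.g. absolute COM
  bias) should be treated as phantom-relative.
* The Σ estimator inherits the σ²/m inflation discussed above; at the
  study's design this is ≈ 3% and is left uncorrected by convention.
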