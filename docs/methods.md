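# Methods

This note documents the generative model, the registration engine, the
response indexes and agreement statistics, the numerical choices behind
them, and what the synthetic study can and cannot say about real reader
studies.

## The measurement problem being modeled

Two CT scans per patient (baseline and restaging across a therapy
interval) are annotated by several readers: 3D segmentations of the whole
pancreas and of the tumor, plus the longest axial tumor diameter and its
in-plane perpendicular. Longitudinal response is then scored six ways —
percent change in longest diameter (%ΔSLD, the RECIST v1.1 index), in the
diameter product (%ΔSDP, the WHO index), in segmented tumor volume
(%ΔV_Seg), in registration-propagated tumor volume (%ΔV_Reg), and the
tumor-burden change Δ%B = (V_T^post/V_P^post − V_T^pre/V_P^pre)·100 in
segmentation- and registration-assisted forms. The scientific question is
how much of the disagreement between readers each index inherits, and how
much an unsupervised image registration removes by eliminating the second
boundary judgement.

## Synthetic cohort generator

The generator defines the study conditions; every downstream statistic is
computed from its output exactly as it would be from real data.

**Phantom.** Grid 96×96×32 voxels at (1.0, 1.0, 2.5) mm — inside the
clinical CT range for abdominal protocols and small enough for
desk-scale registration. The pancreas is a curved tube: a centerline
arcing across the volume with radius tapering 13 → 9 mm (per-patient
jitter ±15%/±5%), rasterized via an anisotropic distance transform. The
tumor is an axis-aligned ellipsoid on the centerline, mean semi-axes
(9, 7, 6) mm jittered ±20%. Intensities: background 30, pancreas 90,
tumor 70 (low contrast against the organ), additive Gaussian noise σ = 5,
then 0.5-voxel Gaussian smoothing.

**Interval change.** The forward map composes a global random
diffeomorphism (exponential of a smooth stationary velocity field,
correlation 20 mm, max amplitude 3 mm) with a local radial contraction
centered on the tumor, plateau over the tumor and blending to identity
18 mm out. The radial scale is calibrated by bisection until the
rasterized warped tumor volume is ρ·V_pre within 2%. The true volume
ratio ρ is drawn per patient from a lognormal (median 0.7, log-sd 0.35,
truncated to (0.1, 1.3)) — mostly shrinkage, occasional growth, matching
a neoadjuvant setting. The stored field is the restaging→baseline
mapping (the direction registration recovers); the restaging image is the
baseline image resampled through it plus fresh noise, and true restaging
masks are nearest-neighbor warps. Positivity of the Jacobian determinant
is verified; non-invertible requests raise.

**Reader model.** A reader's mask is the sublevel set
`SDF(x) ≤ τ + ε(x)` of the true signed distance function, with ε a smooth
zero-mean Gaussian random field (white noise → Gaussian kernel at the
correlation length → rescaled to unit pointwise sd → times σ). Defaults,
per experience × timepoint (mm):

| structure | junior pre/post | senior pre/post | ℓ (corr.) | τ (bias) |
|---|---|---|---|---|
| tumor | 2.0 / 2.6 | 1.6 / 2.0 | 12 | −1.0 |
| pancreas | 1.0 / 1.3 | 0.8 / 1.0 | 20 | 0.0 |

Juniors are noisier than seniors; restaging is noisier than baseline; the
ill-defined tumor carries twice the organ's noise plus a systematic 1 mm
under-segmentation (the direction reported when CT diameters are compared
with resected-specimen measurements). Draws that come out empty — or, for
the tumor, too degenerate to annotate bidimensionally (zero longest or
perpendicular diameter) — are rejected and resampled with an incremented
sub-seed (at most 10 tries): a reader would not submit an unmeasurable
contour. Correlation lengths are set to the
scale of regionally ambiguous boundary stretches (about the structure
scale), a choice made once — boundary errors in real readings are
regional, not voxel-wise speckle. Diameters are *derived from the
reader's own mask* by the exact diameter operations, so diameter noise is
the mask noise seen through an extremal statistic.

The voxel-center EDT used for the SDF overestimates the distance to the
true surface; the mean center-to-surface offset over incidence directions
on rasterized spheres is ≈0.38·spacing, and that offset is subtracted so
the zero level set sits on the surface. With it, a pure τ = −1 mm bias on
a 10 mm sphere at 1 mm spacing reproduces the continuous erosion volume
within 4%.

**Survival.** Exponential proportional hazards: log-hazard = β · z where
z is the cohort-standardized true Δ%B (from true masks) and β = 0.5 per
sd; baseline medians 500 d (OS) and 300 d (RFS); independent uniform
censoring with its upper bound calibrated by bisection to a 30% censored
fraction. β = 0.5 puts the true-marker concordance near the 0.6–0.7
regime typical of imaging markers, and β = 0 gives an exact null for
calibration tests.

**Reproducibility.** One RNG stream per (patient, reader, timepoint,
structure), derived from the master seed through `SeedSequence` tuple
keys: adding readers or patients never perturbs existing draws, and an
identical config reproduces the cohort bit for bit.

## Registration engine

A self-contained log-domain diffeomorphic demons algorithm. A stationary
velocity field v (mm) on the fixed-image grid is optimized greedily over
a 3-level image pyramid (iteration caps 100/80/60, coarse to fine); at
every step the field is exponentiated by scaling-and-squaring (≤ 6
squarings, fewer when the field is small — exactness is preserved by the
half-voxel initial-step rule) and the moving image warped through it.

The default metric is local normalized cross-correlation over a 5³-voxel
window — insensitive to the affine intensity differences that arise
between contrast phases. Its ascent force uses the **symmetric** spatial
gradient (mean of fixed- and warped-image gradients): with a one-sided
gradient the engine showed a systematic sub-voxel boundary bias on
strongly contracting phantoms (volume-change errors of −7 to −11
percentage points at ρ = 0.5–0.7, measured against generator ground
truth); the symmetric force reduces this to ≈ −2 pp. An SSD demons force
is available but not default (it proved prone to folding on these
phantoms).

Each candidate update is fluid-smoothed (σ = 2 mm), scaled to a maximum
step of 1 mm, added to the velocity, and the sum elastic-smoothed
(σ = 1 mm); updates are accepted only if the metric improves (with step
backtracking ×0.6 otherwise), so the metric is non-increasing over
accepted iterations, and optimization stops when the relative metric
change over 5 accepted iterations falls below 1e-4. Images are
percentile-rescaled (1st–99th) to [0, 1] before metric evaluation.
Out-of-volume samples clamp to the nearest edge. The final field must
have strictly positive interior Jacobian determinant (central differences
in physical coordinates) or the call raises.

The engine sees intensities only: the API accepts no masks, so
registration-assisted indexes differ between readers only through their
*baseline* masks — this is the mechanism, not an approximation of it.
Typical performance on default phantoms: mean displacement error over the
pancreas ≈ 0.3–0.5 voxels, sub-voxel inverse-consistency residual,
≈ 3–5 s per patient on one CPU core.

## Response measures

Volumes are voxel count × voxel volume on strictly binary masks (no
partial-volume correction — the convention of the segmentation tools
readers use). The longest axial diameter is the exact maximum pairwise
distance between in-plane voxel centers, per slice (convex-hull pruning,
equal to brute force by construction; ties broken by lowest slice then
lexicographic endpoints). The perpendicular diameter is the extent of
the projection of that slice's voxel centers onto the in-plane normal of
the longest chord — a projection-extent definition, chosen because
real annotation protocols differ on whether the perpendicular must
intersect the longest diameter. The study models a solitary lesion, so
SLD and SDP reduce to the single diameter and single product.

Categories: RECIST v1.1 uses CR on disappearance, PR at ≤ −30%, PD at
≥ +20% (inclusive thresholds — "at least" — so floating-point boundary
cases are deterministic), SD otherwise; the same cutoffs are applied when
%ΔV_Seg or %ΔV_Reg is substituted as the index score. WHO uses −50%/+25%
on the diameter product. Δ%B_Reg replaces only the post tumor volume with
the registered one; the reader's restaging pancreas segmentation still
supplies the denominator.

## Agreement statistics

- **GCI** = Σ_{i<j}|A_i∩A_j| / Σ_{i<j}|A_i∪A_j| over voxel counts; equals
  Jaccard for two readers (and then Dice = 2·GCI/(1+GCI)).
- **CCC/OCCC** use population (1/n) moments, so the J = 2 overall form
  reduces exactly to Lin's coefficient; the overall form is the
  covariance-weighted combination over reader pairs and is bounded by the
  pairwise extremes. Interpretation bands: < 0.3 poor, [0.3, 0.6) fair,
  [0.6, 0.8) moderate, ≥ 0.8 strong (upper-inclusive boundary
  assignment).
- **CCC Z-test**: Fisher-transformed difference with subject-level
  bootstrap standard errors (default 1000 reps, seeded); junior vs senior
  comparisons share subjects and use the paired (joint-resampling)
  variant. The bootstrap replaces a model-based asymptotic variance — it
  is assumption-free and reproducible, not claimed equivalent.
- **Fleiss' κ** with subject-bootstrap CI; an all-one-category table
  makes chance agreement 1 and κ undefined — a sentinel value 1.0 is
  returned with an explicit `degenerate` flag rather than silently.
- **Harrell's C**: higher score ⇒ predicted shorter survival; usable
  pairs are (earlier time has the event) plus tied-time pairs with
  exactly one event; score ties count ½. Implemented vectorized; the
  test suite checks it against an explicit all-pairs enumeration and
  against lifelines on tie-free fixtures.
- **Wilcoxon signed-rank**: zeros dropped, average ranks for ties; exact
  two-sided p for n ≤ 25 via a dynamic-programming convolution over sign
  assignments (doubled ranks are integers even with ties), tie-corrected
  normal approximation beyond. In-package because standard exact
  implementations decline tied ranks.
- Bootstrap CIs everywhere resample *subjects* (percentile, 95%),
  respecting the repeated-measures structure; replicates on which a
  statistic is undefined are dropped.

No multiple-testing correction is applied; p-values are reported raw at
α = 0.05.

## Study pipeline

`run_study` simulates the cohort, registers each patient's pair once
(fields cached on disk keyed by a content hash of the image pair and
parameters), builds one response record per patient × reader, and emits:
GCI tables with Wilcoxon comparisons, OCCC tables for size measurements
and for the six indexes (with junior/senior Z-tests), Fleiss-κ tables for
the four categorization schemes, reader-vs-pathology diameter bias
(t-based CI) and concordance, and Harrell-C tables per index and endpoint
including the true burden change as a ceiling reference. All tables are
CSV; plots are cosmetic renderings of the same numbers. Every bootstrap
seed derives from the config seed, so reports regenerate identically.

## Problem sizes and what the tests show

The default study is 30 patients × 4 readers × 2 timepoints — the
canonical size of a single-center reader study and the size used by the
test suite and acceptance script. Headline qualitative findings (tumor
GCI below pancreas GCI, junior below senior on the organ task, the
CCC ordering %ΔV_Reg > %ΔSLD > %ΔV_Seg, the κ jump under the
registration-assisted index with a collapsed experience gap, negative
pathology bias) are asserted as a majority over five seeded replicate
studies; null calibrations run at n = 200–500 where Monte-Carlo error
permits tight bands; the perfect-reader degenerate limit runs at n = 8
since it is deterministic in the readers, not the cohort size.

**What passing does not show.** The generator's noise is stationary,
symmetric and structure-wise homogeneous; real reader disagreement
includes anatomy-driven ambiguity (vessel interfaces, fibrosis),
protocol differences, and inter-scanner variation, none of which are
modeled. Phantoms share a frame (no affine pre-alignment is exercised),
have a single lesion, and lack CT texture and artifacts. Quantitative
agreement levels therefore calibrate the *pipeline*, not any patient
population; it is the orderings and mechanisms that transfer.

## Known limitations

- The registration engine is a greedy stationary-velocity method; it is
  not a reimplementation of any specific accelerated symmetric-normalization
  algorithm, and its accuracy claims are phantom-scale only.
- Jacobian positivity is checked at voxel resolution; sub-voxel folding
  between grid points is not excluded.
- OCCC inference is bootstrap-only; no GEE/asymptotic variance estimator
  is provided.
- Oblique/rotated image geometries are rejected by design; DICOM
  ingestion and multi-lesion RECIST bookkeeping (target/non-target/new
  lesions) are out of scope.
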