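# Methods

`htpipe` re-implements, as a tested pipeline over a synthetic cohort, a
multiregional multiparametric MRI radiomics workflow for pretreatment
prediction of hemorrhagic transformation (HT) after intravenous thrombolysis
in acute ischemic stroke.  The workflow's central methodological claim is
that regions of interest on the *healthy* (contralateral) hemisphere add
predictive information beyond the lesioned side.  Real patient data for this
problem are not publicly deposited, so the package ships a generative model
of the study conditions and validates the pipeline on it.

## The synthetic cohort generator

**Anatomy.** A shared ellipsoidal "brain" on a regular grid (default
32×32×16 voxels at 1.8×1.8×4.0 mm, the perfusion-map resolution) is
partitioned into the ten arterial supply territories used clinically as ROI
units — anterior cerebral (a), the five middle-cerebral-artery subterritories
(m1–m5), posterior cerebral (p), lenticular nucleus (l), caudate nucleus (c)
and insula (i) — by nearest-seed assignment from anatomically arranged seed
points in the right hemisphere, mirrored exactly onto the left.  The
left–right grid dimension must be even so the mid-sagittal reflection is an
involution on voxels.

**Lesions.** Each patient receives one unilateral lesion: a random ellipsoid
(relative radii 0.12–0.25 of the grid per axis) seeded inside one of the
configured territories (default m1–m5, the typical MCA stroke territories),
clipped to the brain and to the abnormal hemisphere, is the hypoperfusion
envelope; the innermost `core_fraction` (default 0.4, jittered ±15 %) of it
by ellipsoid depth is the infarct core, so core ⊆ envelope by construction.

**Intensity model.** Per sequence `s` with baseline `b_s` (ADC 800, CBF 50,
CBV 4, MTT 6, TTP 25 in their usual units) and voxel noise
`σ_s = noise_sd · b_s` (default `noise_sd` 0.05):

    I(v) = b_s + δ_patient + δ_territory(v)
           + sign_s · S · σ_s · 1[v ∈ lesion]
           + sign_s · O · σ_s · 1[v ∈ abnormal-hemisphere tissue]
           + HT · sign_s · E_ht_ab · σ_s · 1[v ∈ abnormal-hemisphere tissue]
           + HT · sign_s · E_ht_no · σ_s · 1[v ∈ normal-hemisphere tissue]
           + ε(v),   ε ~ N(0, σ_s²)

`sign_s` encodes the pathophysiology: ADC, CBF and CBV fall in the abnormal
region, MTT and TTP rise.  The nuisance terms, all outcome-independent:

- `δ_patient ~ N(0, (0.3 σ_s)²)`, a per-patient per-sequence global offset
  (scanner/physiology variability);
- `δ_territory ~ N(0, (0.2 σ_s)²)`, a per-patient territory offset applied
  symmetrically to both hemispheres;
- `S = E_lesion · max(0, N(1, 0.25))`, the per-patient lesion severity
  (drawn once, shared by all sequences);
- `O = E_lesion · max(0, N(0.25, 0.25))`, a severity-scale oligemia — the
  penumbral hypoperfusion that extends beyond the core over the whole
  lesioned hemisphere.

Severity and oligemia load on the *abnormal hemisphere only*.  That
asymmetric nuisance is the mechanism that makes contralateral ROIs
complementary rather than redundant: every abnormal-side feature carries
per-patient stroke-severity noise unrelated to the HT outcome, while the
mirrored normal-side features are free of it, so a model that sees both
hemispheres has strictly more information than one confined to the lesioned
side.  With all effect sizes zero every lesion- and hemisphere-linked term
vanishes exactly, which is what the null-calibration studies rely on.

**Effect sizes.** All effects are standardized (units of `σ_s`).  Defaults:
lesion effect `E_lesion = 2.0` (a conspicuous lesion, present in every
patient and therefore carrying no outcome signal by itself), HT effect
`E_ht_ab = 1.0` on the brain tissue of the lesioned hemisphere and
`E_ht_no = 0.5` contralaterally — a diffuse hemispheric hemodynamic
derangement in patients who go on to hemorrhage, rather than a purely
core-confined change.  The ⅔ / ⅓ split places most of the HT signal
ipsilaterally while leaving a genuine contralateral component; how much HT
signal is contralateral in real patients is unknown, so this is a modeling
choice made once.  Together with the asymmetric severity/oligemia nuisance
it makes the "All-ROIs ≥ Abnormal-ROIs" comparison a testable property of
the pipeline rather than an accident.

**Outcome and clinical factors.** The HT label is assigned to a fixed
fraction of patients (default 11/71, the reference cohort's rate).  Sixteen
clinical factors are drawn per patient conditionally on the HT group: age as
a truncated normal on [18, 85] centred at 64 (inclusion-criterion bounds,
reference median), and 15 binary factors as independent Bernoulli draws at
the per-group prevalences of the reference cohort (counts / group size).
Under those defaults SVS at initial examination (`svs_1`, 100 % vs 61.7 %)
and an M2 infarct location (36.4 % vs 58.3 %) are the discriminative
factors.  `null_prevalences()` replaces both groups' probabilities with the
no-HT column; the zero-effect ("null") study uses it so that *no* stage —
imaging or clinical — carries label signal.

**What the generator does not emulate.** MRI physics (k-space, partial
volume, motion), registration error, anatomical asymmetry, inter-rater
segmentation variability, correlated clinical factors, and lesion–clinical
dependence.  Passing tests therefore demonstrate that the pipeline recovers
planted signal with the stated geometry and sampling — not clinical validity
on real patients.

## ROI construction

For each territory on the abnormal side the ROI is the territory ∩ (infarct
∪ hypoperfusion); when that intersection is empty the full territory stands
in (its "normal brain area" content), so every patient yields exactly 20
nonempty ROIs — 10 abnormal + 10 mirrored — as the fixed 5400-feature count
requires.  ROIs smaller than 8 voxels are padded by one morphological
dilation inside their territory, because co-occurrence and mesh features
degenerate on near-empty masks.  Mirroring is index reflection about the
mid-sagittal grid plane; nonrigid symmetric registration (needed on real
brains) is out of scope.  Whether infarct- and hypoperfusion-derived ROIs
should be intersected separately per modality rather than as a union is an
open interpretation; the union is implemented.

## Radiomics features (54 per ROI per sequence)

18 first-order, 14 shape and 22 GLCM features, named
`Sequence_Territory_SideClass_Category_Feature`
(e.g. `CBF_a_abnormal_shape_MajorAxisLength`).  Five sequences × 20 ROIs ×
54 = 5400 features per patient; one sequence gives 1080.  Shape features
depend only on the mask and are computed once per ROI, then repeated per
sequence to keep the uniform 20×54 block structure.

Numerical conventions, chosen where the workflow leaves them open:

- **Discretization**: fixed bin count 32 between the in-ROI minimum and
  maximum (scale-free on arbitrary-unit synthetic maps; configurable,
  fixed-bin-width available).  Used for first-order Entropy/Uniformity and
  for the GLCM.
- **Moments**: population (biased) variance; Pearson (non-excess) kurtosis;
  linear-interpolation percentiles.  Energy is the raw sum of squares,
  TotalEnergy multiplies it by the voxel volume.
- **GLCM**: distance 1, the 13 unique 3-D directions, symmetrized,
  normalized per direction, features computed per direction then averaged
  (the common default of the reference radiomics ecosystem).  Logs are base
  2 with 0·log 0 ≡ 0; the matrix is indexed by the gray-level values present
  (`Ng` = number of present levels); a single-level ROI yields the
  constant-image limit (Contrast 0, JointEnergy 1, Correlation 1) instead of
  an error; IMC2 is clamped to [0, 1].  Directions without a single in-mask
  pair are dropped from the average; a mask with no pair in any direction is
  an error naming the ROI.
- **Mesh features**: marching cubes at level 0.5 on the zero-padded mask
  after Gaussian anti-aliasing with σ = 0.6 voxel.  The raw binary mesh has
  a staircase surface whose area overestimates smooth shapes by 6–8 %
  (digital ball sphericity ≈ 0.92); the anti-aliased surface restores the
  analytic limit (≈ 0.98) while remaining deterministic.  Masks too small
  for the smoothed field to cross the iso-level fall back to the binary
  mesh.  Maximum diameters are largest pairwise surface-vertex distances
  (convex-hull accelerated), overall and per coordinate plane.
- **Axis lengths**: `4·√λ` from the population covariance of physical
  voxel-centre coordinates; a single-voxel mask has zero axis lengths,
  Elongation and Flatness.

Every feature is checked against an independent naive implementation
(explicit loops, textbook formulas) to 1e-9 relative tolerance.

## Feature selection

Radiomics features are ranked by the magnitude of L1-penalized linear
regression (coordinate descent, squared loss on the 0/1 label) coefficients
on z-scored columns, keeping the top *k* (default 14).  At the prescribed
penalty α = 1e-6 the fit is essentially a minimum-norm least-squares
solution, so selection is magnitude ranking of near-OLS coefficients; with
p ≫ n this is formally ill-posed, and the implementation relies on the
deterministic coordinate-descent solution (warm start at zero, fixed
iteration cap, non-convergence recorded on the result rather than raised).
Ties in |coefficient| break by column name.  Standardization is on by
default and recorded in the result.

Clinical screening: binary factors by a one-sided Fisher exact test in the
direction of the observed association (this reproduces the reference
SVS_1 p = 0.009 as the hypergeometric tail C(48,11)/C(71,11)); age by a
two-sided rank-sum test; each factor scored as a single-feature classifier
by orientation-free AUC `max(a, 1−a)` (reproducing the reference AUCs 0.692
for SVS_1 and 0.610 for M2).  Selection takes the two highest-AUC factors
among those with p < 0.05, falling back to the top-2 AUC overall when fewer
than two pass — the fallback is what selects SVS_1 + M2 here, since a
Fisher test on the M2 table is not significant.  No multiple-testing
correction is applied (none is applied in the reference workflow); the
p-threshold is configurable.

Fusion: the 14 selected radiomics columns plus the 2 clinical columns are
re-ranked by a second LASSO; features with nonzero coefficients are kept
(≤ 16).

## Modeling and evaluation

The cohort splits once into primary and held-out validation cohorts at the
49/22 proportion (stratified by HT, largest-remainder allocation, ≥ 1 case
of each class on both sides).  On the primary cohort, stratified five-fold
cross-validation trains five random forests (70 trees, depth 5) per
condition; the HT class is rebalanced to parity beforehand with SMOTE
(k = 5 neighbours, synthetic point `x_i + u·(x_nn − x_i)`, `u ~ U(0,1)`).

SMOTE is applied **inside each training fold** by default: oversampling the
whole primary cohort before folding places interpolants of held-out-fold
samples into the training folds, which inflates in-primary CV estimates.
`pooled_smote=True` reproduces that original order for fidelity; validation
metrics are honest either way because the validation cohort never enters
SMOTE or training.  Folds that lose a class degrade `k` rather than fail.

Each fold model is scored on the untouched validation cohort; metrics (AUC
by rank statistic, and ACC/SEN/SPEC/F1 at probability threshold 0.5 — the
threshold is a choice, the reference workflow does not state one) are
reported as mean ± std over the five fold models, matching the reference
table layout.  Degenerate constant scores report AUC 0.5.  The suite runner
produces the four-model comparison (clinical, Abnormal-ROIs, All-ROIs,
combined), the five single-sequence models, the feature-count sweep
k = 5…20, and ROC curves under seeds 100/200/300, and asserts that the
Abnormal-ROIs condition never sees a normal-side column.

## Problem sizes and orchestration

One global seed fans out to per-stage seeds by fixed offsets (+1 split,
+2 SMOTE, +3 forest), so a single integer reproduces a study bit-for-bit
while stages stay independently runnable; stage outputs are cached by
config hash.

The Monte-Carlo studies (null calibration, signal recovery, the
All-vs-Abnormal ordering) use 200-patient cohorts over 10 seeds on a
24×24×12 grid — the package's scaled study grid, chosen so a full
10-seed × 200-patient × 5400-feature experiment is a minutes-scale
computation; the default single-cohort grid remains 32×32×16.  The null
calibration checks each model's *mean* validation AUC over the 10 seeds
against the chance band [0.35, 0.65]: a single-seed AUC on a ~60-patient
validation cohort has a null standard deviation of ≈ 0.1, so any per-seed
band that tight would reject by chance alone; the seed-mean (s.d. ≈ 0.03)
is the statistically meaningful no-leakage check.  Note that feature
selection runs on the full cohort before the split — faithful to the source
workflow — so the selected noise columns retain some chance correlation
with the validation labels and the null radiomics models centre somewhat
above 0.5 rather than at it; the validation cohort itself never enters
SMOTE or forest fitting.

## Known limitations

- Shape features are duplicated across sequences by design (block-structure
  fidelity), wasting 4×14 columns per ROI on identical values.
- The near-zero LASSO penalty makes selection a ranking heuristic, not an
  inferential statement: in the p ≫ n regime almost all coefficients of the
  (fully converged, deterministic) coordinate-descent solution are nonzero,
  and their magnitudes track the minimum-norm interpolator rather than
  marginal informativeness.  On the synthetic study this is the performance
  bottleneck: the acceptance script reports, alongside the shipped
  pipeline's All-ROIs AUC, the recoverable-signal ceiling obtained when a
  univariate-AUC-ranked top-14 replaces the LASSO ranking
  (`oracle_selection_median_validation_auc`); the gap between the two is
  attributable to the prescribed selector, which is kept for fidelity.
- The generator's Gaussian intensity model has no spatial correlation, so
  GLCM features are weakly informative on synthetic data; discrimination is
  carried mainly by first-order and shape features, which is consistent with
  how the selection behaves.
- Real-data concerns — registration, field inhomogeneity, scanner harmonies,
  segmentation variability — are entirely out of scope.
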