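# Methods

## Classification model

Segmentation is voxel-wise supervised classification. For each subject,
every in-brain voxel yields a feature vector whose components are, in
order: one variance-scaled intensity per modality (FLAIR first, T1 and
others optional), one local patch mean per modality per kernel size D,
and three spatially weighted MNI coordinates. A query voxel's lesion
probability is the fraction of lesion-class rows among its k nearest
training rows under Euclidean distance; with k = 40 the output is
quantised to steps of 0.025. The binary mask applies an inclusive
threshold p ≥ θ (θ = 0.9 by default; inclusive so that θ = 1.0 remains
attainable with quantised probabilities, switchable to strict) followed
by the CSF-based exclusion mask.

Assumptions: all of a subject's images live on one voxel grid
(registration is upstream and out of scope; affine transforms are
accepted as FLIRT-style 4×4 text matrices); lesions are hyperintense on
the first modality; training subjects carry consensus manual masks
treated as ground truth.

### Normalisation

"Variance scaling" divides in-mask intensities by the in-mask sample
standard deviation (ddof = 1) without mean-centring; a `center` flag
enables full z-scoring. Patch-mean columns are normalised independently
of their source modality. Spatial coordinates are divided by their
per-axis in-mask standard deviation and multiplied by sw, so the
coordinate columns have variance sw² — sw = 0 removes them, sw = 1
puts them on the intensity scale, large sw makes the classifier a
location prior.

### Neighbour search and tie-breaking

The production path is a KD-tree (scikit-learn `NearestNeighbors`). Ties
at the k-th neighbour distance are resolved by training-row insertion
order: the tree is queried for k + 1 neighbours, and any query whose
k-th and (k+1)-th distances agree within 1e-9 relative is re-resolved by
an exhaustive stable lexicographic (distance, row index) sort. The same
exhaustive routine is kept as an independent oracle; tests assert exact
probability equality between the two paths.

## Training-set construction

Per subject, lesion voxels are sampled uniformly without replacement
from the manual mask (FE/FU: up to n_wmh = 2000; AE: all), and
non-lesion voxels from the in-brain complement according to the
location option: `any` (whole pool), `no_border` (excluding a 1-voxel
26-connected shell around lesions — the shell width is configurable
since "close to the edge" has no canonical width), or `surround`
(preferentially the shell, falling back to the general pool with a
logged warning when the shell is too small, so class counts stay
feasible). FE and AE match the non-lesion count to the *actually
selected* lesion count (the "equal" reading when the cap binds); FU
uses its own budget (default 10000). Subject selection may restrict
training to the n highest- or lowest-load subjects, with load scores
from visual ratings or manual-mask volume and lexicographic id
tie-break.

Per-subject sampling seeds are derived from the configuration seed and
a hash of the subject id, making each subject's contribution invariant
to cohort composition — this is what makes leave-one-out exact: the
training pool for subject s is literally the pooled rows of everyone
but s. Feature normalisation is per subject, from its own brain mask.

## Exclusion mask

A two-class intensity split of FLAIR separates dark CSF from brain
parenchyma. It is implemented as a 1-D Gaussian mixture with **tied**
variances, initialised at the 5th and 60th intensity percentiles: tying
the variances keeps the fit a coarse dark-vs-bright partition and
prevents the degenerate solution in which one component locks onto the
narrow white-matter mode and the "low" component absorbs CSF, grey
matter *and* lesions (observed with unconstrained covariances at high
lesion load). No spatial regularisation is used; the split only needs
to be coarse.

Ventricular CSF, identified from an atlas ventricle label and enlarged
by a 2-voxel protective margin, is removed from the CSF map so that
periventricular lesions are never masked. The remaining cortical CSF is
dilated (26-connected, default 2 iterations — enough to cover a
cortical grey-matter ribbon of ~2 voxels; dataset-dependent and
configurable) and united with atlas-labelled subcortical structures
(thalamus, basal ganglia, entorhinal cortex by default; cerebellum can
be added as another label). Candidate lesion voxels inside the union
are discarded. Consequence: cortical and cerebellar lesions are
undetectable by design.

Interpolated binary masks (e.g. a manual mask resampled after
registration) are re-binarised at a strict > 0.25 threshold; the
inclusivity is configurable since only "thresholded at 0.25" is
conventionally specified.

## Evaluation metrics

SI, voxel FPR/FNR, cluster FPR/FNR, DER and OER follow the standard
cluster-matching convention: an automated cluster touching the manual
mask by ≥ 1 voxel is a detection (no overlap-fraction requirement);
clusters are 26-connected by default (8-connected in-plane mode
available for strongly anisotropic data). DER pools the volume of
unmatched clusters, OER the non-overlapping volume of matched ones,
both divided by the mean total volume of the two masks; with these
definitions DER + OER = 2(1 − SI) identically, which the tests verify
to 1e-9 on random masks. Empty-vs-empty comparisons are defined as
perfect (SI = 1, errors 0); 0/0 ratios elsewhere report 0.

ICC is the single-measure, absolute-agreement, two-way model
coefficient, computed from the ANOVA decomposition
(MSR − MSE)/(MSR + MSE + (2/n)(MSC − MSE)) for two raters; it is
cross-checked in tests against an independent brute-force ANOVA and
against `pingouin`'s ICC(A,1). WMHr is lesion volume as a percentage of
intracranial volume; its log transform uses ε = half the smallest
nonzero cohort WMHr for lesion-free subjects. Scan-rescan agreement
reports per-pair percentage error 100·|v₁−v₂|/mean, Bland–Altman mean
difference with ±1.96·sd limits, Spearman ρ and ICC.

## Option optimisation

The grid search scores each configuration by leave-one-out evaluation
(mean ± sd SI, cluster FNR, volume ICC) and selects lexicographically:
max mean SI, then max ICC, then min cluster FNR — a formalisation of
the priority "overlap first, volumes second, missed clusters third".
The order is configurable because different studies weigh these
differently; exact ties return all co-optimal configurations. Phase 1
varies one axis at a time around a fixed baseline; phase 2 re-varies
each axis around the combined winners. Full-factorial expansion exists
but is not the default.

## Phantom generator

The phantom emulates the properties the classifier actually exploits:
a layered ellipsoidal head (outermost cortical-CSF shell, 2-voxel
grey-matter ribbon, white-matter core, paired lateral ventricles,
thalamic/basal-ganglia nuclei, small entorhinal regions), lesions built
from half-max-thresholded Gaussian blobs clipped to white matter
(reproducing both punctate and confluent periventricular morphology; a
configurable fraction seeds adjacent to the ventricles), FLAIR-like
contrast ordering lesion > WM > GM > CSF, a pseudo-T1 with lesions
mildly hypointense, partial-volume Gaussian smoothing, and additive
Gaussian noise. The phantom's standard space is its own grid (identity
subject-to-MNI affine). Lesion growth trims the final blob so the
achieved load matches the requested fraction of WM volume exactly.

Default rendering: tissue means CSF 25 / GM 70 / WM 100 (arbitrary
units), lesion 1.5 × WM, noise sd 0.08 × WM mean (SNR ≈ 12, typical of
clinical FLAIR), partial-volume FWHM 1.5 mm on a 1 mm grid. At these
values confluent high-load lesions are recovered well while punctate
low-load lesions lose contrast to partial volume — the
load-dependence of difficulty seen in real cohorts. What the phantom
does **not** model: Rician noise statistics, bias fields,
gyral/sulcal anatomy, anisotropic acquisition artefacts, flow-related
ghosting (a simplified fourth-ventricle-style bright artefact can be
planted), and inter-rater variability of manual masks. Passing tests
therefore demonstrate algorithmic correctness and qualitative
behaviour, not clinical-grade accuracy on real data.

Structural draws (anatomy, lesions, artefact placement) and noise use
separate random streams, so the same anatomy can be re-rendered as an
independent noise realisation for scan-rescan experiments.

## Reference study sizes

The bundled studies (`wmhseg.study`) use 12 mixed-load 64³ phantoms
(training on the 6 highest-load) for recovery and volumetric ICC, 10
mixed-load 48³ phantoms × 2 noise realisations for reproducibility,
and 3 artefact phantoms for exclusion efficacy — sizes chosen so the
full self-evaluation completes in a couple of minutes on one CPU while
keeping ≥ 10 subjects where a correlation or ICC is computed.

## Numerical and degenerate-input conventions

Standard deviations use ddof = 1 throughout. Constant in-mask images,
constant correlation inputs, k larger than the training set, empty
non-lesion pools, and ICC with zero between-subject variance all raise
errors rather than returning NaN. Subjects with empty manual masks are
skipped with a warning (they cannot contribute lesion rows). Even patch
kernels anchor floor((D−1)/2) voxels before / ceil((D−1)/2) after the
centre. Out-of-field voxels in resampling are 0 (background). Voxel
indices are 0-based; world coordinates follow the NIfTI affine in mm.

## Known limitations

Only affine subject-to-MNI transforms are supported. The exclusion mask
requires atlas labels (ventricles at minimum). The tie-break at the
k-th neighbour is deterministic but arbitrary. Longitudinal use and MS
lesion segmentation are out of scope, and the optimiser does not try
every factorial combination of options.
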