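# Methods

This note documents the models, conventions and numerical choices behind
`lesionwise`, in the order the pipeline applies them.

## Data model and orientation

All volumes are 3D scalar lattices with per-axis voxel spacing in mm; the
physical coordinate of voxel (i, j, k) is (i·sx, j·sy, k·sz) (voxel-center
convention). On load every NIfTI volume is reoriented via its affine to a
fixed anatomical convention — axis X grows toward the anatomical left,
Y toward anterior, Z toward superior ("LAS") — so that the signs of
positional offsets and half-brain asymmetries are deterministic and do not
depend on how files were stored. Verbal directions like "more lesions on
the left" only mean something under a declared convention; this is ours,
and every offset the toolkit emits uses it.

2D inputs are rejected rather than auto-promoted: components, centroids
and volumes are defined volumetrically, and silently treating a slice as a
thin volume would produce counts that are not comparable across cases.
Masks read from disk are binarized at `value > 0.5` by default, which
tolerates interpolation residue in resampled masks.

## Whole-volume metrics

DSC, sensitivity and precision are computed from exact voxelwise TP/FP/FN
counts. A metric whose denominator is zero (e.g. precision of an empty
detection) is *undefined*: it is carried as NaN, excluded from every
aggregate, and surfaced as a warning. Mapping it to 0 or 1 instead would
bias cohort means in opposite directions; exclusion keeps the aggregates
interpretable and the sample size explicit (reported as `n`).

Cohort statistics report mean, population standard deviation (ddof = 0, so
a single case has std 0), median, 25th/75th percentiles (linear
interpolation between order statistics), min and max. Cases are stratified
by GT volume into [0, 10), [10, 100] and (100, ∞) cm³; both edges of the
middle stratum are inclusive, the choice is arbitrary but fixed and
documented (volume values landing exactly on an edge are rare in practice
but must be deterministic). Strata are summarized by per-case averaging;
a voxel-pooled alternative (`pooled_metrics`) is available when a stratum's
small cases should not dominate its mean. The GT-vs-detected volume
correlation is Pearson's product-moment coefficient by default, with
Spearman available by configuration for users who prefer a rank-based
reading.

## Component analysis

Connected components are labelled with 6- or 26-neighborhood rules
(26 default — the common clinical convention in 3D); labels are renumbered
in scan order of each component's first voxel so labelling is fully
deterministic. The two sides are processed symmetrically and
independently.

Per-component DSC is computed against the union of all opposite-side
components sharing at least one voxel with the component:

    DSC(c) = 2·|c ∩ U| / (|c| + |U|),  U = union of overlapping counterparts

Zero-overlap components score 0 (not undefined). Alternatives were
considered and rejected: scoring against the full opposite mask would let
remote components distort the score, and one-to-one matching (Hungarian or
best-overlap assignment) forbids the clinically real situation where one
confluent detection covers several distinct GT lesions. No exclusivity is
enforced — a single detection may render several GT components Found.

Categories use inclusive boundaries exactly as defined: Found at
DSC ≥ 0.5, Partially Found at 0.05 ≤ DSC < 0.5, Missed below 0.05; both
thresholds are configurable. Category tables report counts, percent of
components, and percent of the side's total component volume; raw values
are kept in machine output and rounded to one decimal only at rendering.
The threshold sweep reports, for each τ in 0.05…0.95 (step 0.05), the
number and cumulative volume of components with DSC ≥ τ on each side;
both are non-increasing in τ by construction.

## Positional analysis

The brain center is the unweighted centroid of the brain mask (geometric
center of tissue); a bounding-box mode exists for sensitivity checks,
since "center of the brain" admits both readings. Component centroids are
voxel-count centroids (not intensity-weighted — the masks, not the images,
define the components). Offsets are centroid − center, in mm, signed per
the orientation convention.

Half-brain asymmetry per axis and category is
100·(N⁺ − N⁻)/(N⁺ + N⁻), where N⁺/N⁻ count components with strictly
positive/negative offset; exact-zero offsets belong to neither half, and a
category with no off-plane components reports NaN. The denominator is the
category total in both halves; a "percent more than the smaller half"
reading would be unbounded and is not used. Axis histograms use 10 mm bins
centered on zero (bin k covers [k·w − w/2, k·w + w/2)), matching the
±20/±40 mm granularity at which such distributions are usually discussed.

## Intensity analysis

The intensity difference of a component in one modality is
ID = 100%·(mean_component − mean_VOI)/mean_VOI against a healthy
white-matter VOI supplied per case (one VOI for all modalities). GT-side
records average over the GT component's voxels, detection-side records
over the detection component's voxels. ID is invariant under a pure
positive rescaling of the modality but **not** under affine maps with an
offset, so the normalization order is part of the contract: the optional
12-bit stretch (linear map of [min, max] onto [0, 4095]; constant grids map
to zero) is applied *before* ID when enabled, and inputs that are already
normalized should be evaluated with the stretch disabled. A VOI mean of
zero makes ID undefined (NaN, reported).

## Phantom generator

The generator emulates the data structure the evaluation consumes, not MRI
physics: a spherical brain, ellipsoidal lesions, piecewise-constant
modalities plus optional Gaussian noise. What it reproduces exactly —
component counts, volumes, positions, per-component DSC, planned ID — is
precisely what the evaluation measures; what it does not reproduce
(irregular lesion shapes, bias fields, partial-volume effects, anatomy)
means a passing pipeline says nothing about segmentation *models*, only
that the *measurement machinery* is correct.

A lesion with target volume V is realized as the N = V/voxel-volume voxels
closest to its center under the ellipsoid norm (stable scan-order
tie-breaks), putting the realized volume within half a voxel of target and
the centroid within a fraction of a voxel. A detection with target
per-component DSC t takes a nested prefix (shrink) or superset (grow) of
the same distance ordering; for a shrink, DSC = 2·n_det/(n + n_det)
exactly, so n_det = round(n·t/(2 − t)) realizes t up to count granularity
(the realized value is recorded in the truth table). Lesions below 30
voxels cannot hold an intermediate DSC target at that granularity, so
their plan degrades to exact-copy (Found) or drop (Missed). Specs whose
lesions would merge into fewer connected components than planned are
rejected as unrealizable rather than silently renumbered.

Modalities are background-level (default 1000, a mid 12-bit value) inside
the brain, zero outside, and background·(1 + ID/100) on lesion voxels, so
the planned ID is exact before noise; the healthy VOI is a sphere placed
at maximal clearance from every lesion and false positive, guaranteeing
disjointness or failing loudly. Noise is additive Gaussian on the
intensity grids only — masks stay clean, since the framework evaluates
given masks. Generation is a pure function of the spec; one seed gives
bit-identical bundles.

Default cohort conditions (fixed once): 96³ grid at 1 mm isotropic
spacing, brain radius 42 mm, 3–12 lesions per case with volumes
log-uniform on [1, 3·10⁴] mm³, 1–6 false positives of 1–100 mm³, and
per-modality ID ranges FLAIR +25…+65%, T2 0…+70%, T1ce −30…+20% —
spanning the contrast ranges typical of hyperintense lesions on
FLAIR/T2 and iso-to-hypointense behavior on T1ce. Category assignment is
volume-conditional to mirror the clinical pattern the framework exists to
expose: components above 200 mm³ are always planned Found (detectors find
the big ones), smaller components split between Partially Found and
Missed (ratio 27:24), so Found components span every volume, failures
concentrate at small volumes, and most of the total abnormal volume is
detected. DSC targets are drawn from [0.65, 0.95] for Found and
[0.12, 0.42] for Partially Found — inside the category bands, so count
granularity cannot flip a planned category. Placement uses rejection
sampling with a 2-voxel clearance margin between lesion reach spheres;
lesions that cannot be placed after repeated tries shrink by 4× and retry,
keeping generation total and deterministic.

## Report assembly

Category tables, the sweep, positional and intensity summaries pool
components across the whole cohort (counts over all cases), matching how
multi-exam component statistics are normally tabulated; per-case rows
remain in the component table for per-case analyses. Unreadable manifest
rows are skipped with a warning and an all-skipped cohort is a hard error;
warnings never change the exit status. Text tables round metrics to two
decimals and percentages to one; `report.json` keeps full precision and
round-trips losslessly.

## Problem sizes used in verification

The self-checks run on phantom cohorts of 24 cases at 96³ voxels
(mirroring the 24-exam validation-cohort structure the component counts
come from), labelling-oracle comparisons on exhaustive 3×3×1 and sampled
3³/6³ grids, and single-case phantoms for identity, boundary and
intensity-recovery checks. These sizes exercise every code path the
full-resolution (256×256×k) clinical case would, since all operations are
resolution-agnostic.

## Known limitations

- No anatomical-atlas localization: positions are offsets from the brain
  center, not region labels (deep white matter, cerebellum, …).
- One healthy VOI per case; per-modality VOIs are not supported.
- No instance matching (Hungarian/panoptic schemes) — by design, see above.
- The phantom brain is a sphere; half-brain asymmetries on phantoms test
  bookkeeping, not anatomy.
- Physical-unit results require correct voxel spacing in the NIfTI
  headers; the toolkit never guesses spacing.
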