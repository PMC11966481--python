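# Methods

This note documents the models and procedures `corticalmark` implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer should know about.

## Regional homogeneity (ReHo)

ReHo measures the temporal coherence of a voxel's BOLD series with its 3×3×3
neighborhood (27 voxels including the center) via Kendall's coefficient of
concordance.  Each of the K series is converted to midranks over the T
timepoints; with rank sums R_t and per-series tie correction
C_k = Σ_groups (g³ − g),

    W = 12 Σ_t (R_t − K(T+1)/2)² / (K²(T³ − T) − K Σ_k C_k).

W ∈ [0, 1]; under independence E[W] = 1/K (the Friedman statistic
K(T−1)W is approximately χ²(T−1)).

Decisions:

- **Ties.** Midranks with the standard tie-correction term.  Continuous BOLD
  rarely ties, but quantized or synthetic data can; the corrected formula
  degrades gracefully and reduces to the textbook form without ties.
- **Mask edges.** W is computed over whichever of the 27 neighbors fall
  inside the mask, with a `min_neighbors` floor (default 2); the K actually
  used is recorded per voxel.  This keeps cortical-ribbon voxels rather than
  discarding everything without a complete neighborhood.
- **Constant series** carry no rank information and make the tie-corrected
  denominator degenerate, so they are excluded from the neighborhood before
  W is computed; if K then falls below the floor the voxel is NaN.
- **No spatial smoothing** is applied before ReHo (smoothing mechanically
  inflates W); preprocessing is out of scope for this package.
- Regional reduction is the arithmetic mean over defined voxels, followed by
  bilateral (L+R)/2 averaging per subject; if either hemisphere is undefined
  the bilateral value is NaN.

## Effect-size maps

Each region's measure is residualized on [1, age, sex] by ordinary least
squares, fitted **diagnosis-blind on the pooled sample** (a controls-only
mode is available), and re-centered at the covariate means so the measure
keeps its scale.  Pooled residualization is the common companion practice to
effect-size packages; fitting on controls only is preferable when case
covariate effects are suspected to differ.  Per region, Cohen's d
(case − control, pooled SD) is computed with the two-sample t statistic and
two-sided p from t with n₁+n₂−2 df.  Classic d is the default; a Hedges
small-sample factor is available but off, since d is the convention in the
large-cohort literature this mirrors.  Per-region significance uses
Bonferroni over the R regions present in the input (R is never hard-coded);
Benjamini–Hochberg is available via `correction="fdr_bh"`.

Map-level inference (is map A similar to map B?) is deliberately separate
from per-region inference and handled by the spin test.

## Spin permutation test

Regional maps live on parcels with spherical centroid coordinates.  The
null for a map–map correlation preserves each map's values and approximate
spatial arrangement: all centroids are rotated by a rotation drawn uniformly
from SO(3) (Gaussian QR with sign fixing, one column flipped if det = −1),
and every parcel takes the value of the parcel whose *original* centroid is
nearest to its rotated position.  Sampling with replacement (duplicate
assignments) is allowed, as is standard for parcel-level spin tests.  Only
map A is permuted.  The two-sided p-value uses +1 smoothing,
p = (1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1), so it is never 0 and never
below 1/(n_perm+1).  Default n_perm = 999.  Bilaterally averaged maps are
spun on left-hemisphere centroids.  NaN regions are dropped pairwise with a
warning; permutations that degenerate to zero variance count as r = 0.

Calibration: on iid Gaussian map pairs over 34 generic unit-sphere centroids
the empirical type-I error at α = 0.05 over 400 replicates of 999 spins sits
in the nominal range (the acceptance script recomputes this).

Fisher's r-to-z comparison of two map correlations uses
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)) with a two-sided normal p.
The region count n is always an explicit argument.

## Regional Vulnerability Index

RVI quantifies how strongly one subject expresses a template deficit
pattern.  After the same covariate adjustment as the effect maps, a
control-only reference (mean μ_j, sample SD σ_j per region; zero-SD regions
excluded with a warning) converts each subject to z-deviations
z_ij = (x_ij − μ_j)/σ_j, and

    RVI_i = Pearson correlation across regions between z_i· and d_template.

Templates are stored as case − control d (deficits negative), so a subject
whose deviations follow the deficit pattern scores **positively**.  RVI is
invariant to positive affine rescaling of the template and flips sign under
negation.  Pearson correlation is the default kernel (the established RVI
definition); Spearman and cosine are selectable.  Region matching is by
canonicalized (lowercase/underscore) name because templates and cohort
tables typically originate from different tools.  Z-scoring is against the
target cohort's own controls by default — whether to normalize within-cohort
or against an external norm is genuinely open; both the reference sample
(`adjustment`, controls-only reference) and the kernel are explicit
parameters rather than hidden defaults.

Group contrasts use pooled-SD Cohen's d with a two-sample t test; symptom
associations use Pearson r over subjects with non-missing severity (controls
typically have none).

## Synthetic-data generator

The generator exists because the cohorts this kind of analysis is run on are
restricted-access; it produces every input the pipeline needs with known
ground truth.

- **Toy atlas**: mirrored rectangular blocks on a grid, P region pairs,
  labels 1..P (left) and P+1..2P (right), centroids = mean voxel coordinate
  relative to the grid center projected to the unit sphere, so L/R pairs
  mirror exactly.  Deterministic geometry; the seed only permutes region ids.
- **BOLD**: voxel series in region j is √c_j·(shared region signal) +
  √(1−c_j)·(voxel noise), standard Gaussian innovations scaled by
  `noise_sd`; background voxels get independent noise.  The shared-variance
  fraction c_j ∈ [0, 1) maps monotonically onto regional ReHo (c = 0 gives
  the 1/K null; c → 1 drives W → 1), which is what makes planted functional
  deficits possible.
- **Regional cohorts**: x_ij = mean_j + β_age,j·age_i + β_sex,j·sex_i +
  dx_i·d_j·σ_j + ε_ij with ε ~ N(0, σ_j²), ages Uniform(20, 70), sex
  Bernoulli(0.5) coded 0/1.  `age_case_shift` adds a constant to case ages to
  create a confounded design for testing adjustment.  Severity is generated
  for cases only (controls get NaN, exercising missing-data handling):
  an affine, hence monotone, function of the case's standardized
  pattern-expression score Σ_j d_j z_ij mixed with Gaussian noise to hit a
  target correlation (`severity_link`, default 0.4 — a realistic
  biomarker–symptom coupling), placed on an HDRS-like 18 ± 6 scale.
- Regional noise is Gaussian and independent across regions — deliberately
  free of spatial autocorrelation so each stage's contract is tested in
  isolation.  Consequently, passing tests show the estimators and their
  calibration are correct under the stated model; they do not show
  robustness to spatially autocorrelated noise, scanner drift, motion,
  hemodynamics, or site effects, none of which are modelled.

All generators are pure functions of their seed; identical configs reproduce
bit-identical tables.

## Pipeline

Stages (simulate → reho → esmap → spin → rvi) communicate only through files
(TSV with tab delimiter, '.' decimal, NaN spelled `NA`; NIfTI-1 volumes;
JSON summaries).  Each stage seeds its own RNG stream from the master seed
hashed with the stage name, so adding a stage never perturbs another's
draws; a manifest (config, per-stage seeds, output digests) accompanies
every run, and replaying a config is byte-identical.

## Problem sizes and numerical choices

The default end-to-end run simulates a 24³ grid, 8 region pairs, T = 60
timepoints, 30 cases + 30 controls — sizes at which the whole chain (60
voxelwise ReHo maps included) completes in a few minutes on one CPU.  At 30
per group a field-realistic deficit (d ≈ −0.3) would be statistically
invisible, so the pipeline's default planted coherence deficit is strong
(per-pair drop of 0.02–0.15 in shared-variance fraction, scaled per case by
an individual severity factor N(1, 0.3²)); this makes the planted pattern
detectable end-to-end at desk scale, at the cost of an unrealistically large
synthetic effect magnitude.  Statistical calibration checks (spin type-I
error, KCC null mean, RVI null mean) use their natural sizes (400×999
spins, 2000 neighborhoods, 10 000 subjects) since they are cheap.

Other numerics: midrank ties are compared exactly (midranks are multiples of
0.5); Kendall denominators ≤ 0 (all series fully tied) yield NaN rather than
raising; covariate designs are rank-checked and singular designs raise
naming the cause; p-values from permutation are +1-smoothed; TSV floats are
written with %.10g so replays are byte-identical.

## Known limitations

- Parcel-level spin tests are approximate: with few parcels or strongly
  clustered centroids the nearest-centroid reassignment duplicates values
  and the null can be mildly anticonservative.
- Pooled diagnosis-blind residualization partially absorbs a true group
  effect when covariates are confounded with diagnosis; the residual bias is
  small (see the acceptance numbers) but not zero, and the controls-only
  mode trades it for a different bias when control covariate slopes differ.
- Recovery of a planted per-region pattern is limited by the sampling error
  of Cohen's d (SD ≈ √(4/N) per region), not by the implementation; at 500
  per group a pattern spread of SD ≈ 0.14 caps the expected recovery
  correlation near 0.92.
- The ReHo↔coherence link is assessed within regions; voxels at region
  boundaries mix shared signals from adjacent regions and have lower W by
  construction.
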