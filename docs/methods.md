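# Methods

This note documents the models, estimators, conventions and synthetic-data
assumptions behind `cortexg`, in the spirit of the methods documentation of
packages like statsmodels or msprime: enough detail to audit every number
the pipeline produces.

## Expression QC

Donor-level profiles arrive in long format (donor, region, gene, value; one
value per triple, multiple samples per donor are averaged first). The
working matrix is the across-donor **median** per (region, gene).
Consistency filtering computes, per gene, the Spearman correlation between
each donor's left-hemisphere regional profile and the cross-donor median
profile, averages over donors, and retains genes with mean ρ strictly
above the threshold (default **0.446**, the conventional one-sided p < .05
calibration for this statistic; it is a configuration constant, not
recomputed from the region count). Conventions:

* the median profile includes the donor under comparison (no
  leave-one-out); a `hemisphere` argument allows the right hemisphere;
* an undefined ρ (a donor profile constant across regions) contributes 0
  to the donor average — conservative, pushing degenerate genes toward
  exclusion;
* ties get average ranks. Because the filter sees only ranks it is
  invariant to monotone increasing transforms of expression; note the
  across-donor *median* is monotone-equivariant only for odd donor counts
  (for even counts it averages two order statistics), so exact invariance
  of the full report holds at odd n.

## Components

PCA runs on the **correlation matrix of genes across regions**: each gene
is z-scored across the 68 regions (population SD), so eigenvalues sum to
the gene count, the variance share of component j is eigenvalue_j / p, and
loadings (eigenvector × √eigenvalue) are gene-component correlations
bounded in [−1, 1] — consistent with the |loading| > 0.3 threshold sets
the package reports. Internals use the SVD of the standardized matrix; the
test suite checks it against an independent eigendecomposition.

**Varimax** is applied to the k retained loading columns with Kaiser row
normalization, convergence tolerance 1e-10 on the rotation criterion, at
most 1000 sweeps (the SVD-based pairwise-free update). Orthogonal rotation
preserves row communalities and the within-subspace variance total, so the
rotated shares sum to the unrotated shares — an internal identity the
acceptance tests assert at 1e-8.

**Sign convention**: each component is oriented so its mean loading is
non-negative. The direction of a principal axis is mathematically
arbitrary; a deterministic rule makes runs reproducible and leaves the
reported solution invariant to a global sign flip of the input (scores, of
necessity, flip with the data).

**Scores** are the standardized projections of the z-scored data on the
rotated loadings. `scale_scores_by_hemisphere` re-standardizes each
component's scores within each hemisphere (mean 0, SD 1, sample SD). This
removes additive hemisphere-level artifacts: in the motivating atlas the
right hemisphere derives from 2 donors versus 6 on the left, which shifts
raw expression — and hence raw scores — by hemisphere even though the
relative regional patterns agree strongly across hemispheres. Score
*magnitudes* are convention-dependent; congruence and correlations, which
are scale-free, are the quantities downstream stages consume.

Missing regional values are not imputed; genes with any missing region are
dropped and recorded on the solution. Constant genes are an error naming
the offending columns.

## Congruence

Tucker's φ is the cosine of two loading vectors. Components of two
solutions are matched greedily by maximum |φ| (matching by congruence, not
index, so e.g. the second component of one dataset may pair with the third
of another). Region-subset cross-validation partitions the regions into
n_folds near-equal parts (sizes 13/14 at 68 regions, 5 folds), refits the
full PCA — including rotation, by default — on each fold and its
complement, and records matched |φ| per component; 50 repeats × 5 folds =
250 comparisons at defaults, all driven by one seed, bit-for-bit
reproducible.

A subtlety the tests document: on *exact* rank-k data every unrotated
subset refit spans the same gene-space plane, so unrotated CV congruence
is exactly 1. The rotated path is not exactly 1 even without noise,
because genes are re-standardized within each subset and the planted score
columns are generally oblique within a small subset; varimax then resolves
that obliqueness differently in each subset. The exactness invariant is
therefore asserted on the unrotated path, and rotation is a flag
(`rotate=False`) on `region_subset_cv`.

Matched-gene congruence restricts two solutions' loadings to their shared
gene identifiers (optional id maps translate namespaces; ≥ 10 shared genes
required) — this is the entry point for comparing externally produced
solutions (other pipelines, atlases or parcellations), which the package
deliberately does not regenerate itself.

## Latent g

Per cohort, the measurement model is a single common factor:
xⱼ = μⱼ + λⱼ g + eⱼ with Var(g) = 1 (identification by fixed factor
variance, not a marker loading, so λ is comparable across cohorts and g is
unit-scaled), residuals independent except for optional within-domain
residual covariances supplied as named groups of tests (emulating
multi-domain batteries). Estimation is **FIML**: the Gaussian
log-likelihood is accumulated per missingness pattern on each subject's
observed subvector; on complete data this reduces exactly to
covariance-based ML, and the implementation uses the sufficient-statistic
form there for speed (the equality is a test). Tests are first
residualized on age and sex (per-test complete cases).

Optimization is L-BFGS-B with numerical gradients from moment-based
starting values; non-convergence triggers up to three perturbed restarts;
the convergence record (gradient norm, restarts) is kept on the model.
Negative residual variances are *flagged* as Heywood cases, not truncated.

The model χ² is the likelihood ratio 2(llₛₐₜ − llₘₒdₑₗ) (equal to N·F_ML
with the biased sample covariance on complete data — the lavaan
convention); the saturated model under missingness is fit by EM for the
unrestricted mean/covariance, and the independence baseline factorizes
exactly per variable. CFI, TLI, RMSEA (√(max(χ²−df,0)/(df·N))) and SRMR
(RMS of correlation-scale residuals including the diagonal) follow the
standard ML formulas; df = 0 reports RMSEA 0 and TLI as missing.

Factor scores use the regression method, g = λᵀΣ⁻¹(x − μ) on the observed
subvector, oriented so g correlates positively with the mean standardized
test score (the extraction method is not dictated by the analysis being
emulated; the regression method is the default choice and the orientation
rule makes the arbitrary factor sign deterministic).

## Meta-analytic mapping

Per (region, measure, cohort): measure values more than 4 SD from the
region mean are excluded (strict inequality; exclusion precedes
standardization), then g and the measure are z-scored on the analysis
sample and the measure is regressed on g plus covariates — age, sex,
centered head-position coordinates, test lag, and site as indicator
contrasts with the largest site as reference. The g coefficient is the
standardized β (both variables standardized; the "standardize measure, g,
or both" convention is not uniquely determined by the source analyses —
both-standardized is used and noted here). Collinear covariate columns are
dropped with a warning and flagged on the estimate.

Pooling is inverse-variance random-effects: τ² by **REML** (bounded 1-D
optimization of the restricted likelihood; cross-checked against R
`metafor` to ~1e-7 in the tests) with **DerSimonian-Laird** as the
closed-form option and test oracle; Wald CI and two-sided normal p. With
one study the estimate passes through flagged. Mean-age moderation uses a
mixed-effects meta-regression (intercept + centered moderator) with REML
τ²; k = 2 is flagged untestable (0 residual df). Whole-cortex adjustment
recomputes regional βs adding the total (sum for volume/surface area, mean
for thickness) as a covariate and reports the correlation between adjusted
and unadjusted pooled profiles.

## Spatial association and gene/cell-type scans

Regional maps are Series keyed by hemisphere-tagged labels; associations
are plain Pearson correlations with two-sided t p-values on n − 2 df,
treating regions as exchangeable — **no spatial-autocorrelation (spin)
correction is applied**, deliberately matching the analysis being
emulated; this is a known limitation (regional values are spatially
autocorrelated, so the nominal p-values are anti-conservative for real
maps). Interhemispheric mode pairs the 34 lh/rh labels and rejects
unpaired labels. The absolute-score association correlates |score| with a
β map; the quadratic variant regresses the β map on the signed score and
its square (with centered, mean-zero scores the intercept plus quadratic
term × mean squared score reproduces the map mean — asserted in tests).

The gene scan hemisphere-scales every gene (z within hemisphere; genes
constant within a hemisphere are excluded and recorded), then per gene and
measure fits OLS of the pooled β map on [1, gene, score₁, score₂] across
the 68 regions — unweighted, as no meta-analytic-SE weighting is specified
in the emulated analysis. A design condition number above 1e8 sets an
instability flag instead of failing. BH FDR runs within each measure; the
Q < .05 sets are intersected pairwise and three-way. Cell types: the mean
profile of each type's genes is hemisphere-scaled and regressed the same
way (FDR across the type × measure grid); loading distributions use the
tie-corrected Kruskal-Wallis H over all groups plus Dunn z tests of each
type against the `unclassified` baseline, Holm-adjusted (full pairwise is
out of scope by default), with moment-based Fisher-Pearson skewness g₁ and
excess kurtosis g₂ (the estimator type is a convention choice; values of
other types differ slightly).

## Synthetic data: what it emulates, and what it does not

No generative model exists for these data in the literature; every
distributional choice below is an explicit stand-in, chosen once to be
realistic for log2-scale microarray summaries and adult population
cohorts. Defaults (all in `SyntheticConfig`):

* **Planted scores**: per seed, orthogonal centered unit-variance columns
  per hemisphere, right hemisphere = 0.8·left + √(1−0.8²)·independent
  (mirror correlation 0.8, emulating observed interhemispheric score
  correlations ~0.7-0.8).
* **Loadings**: simple structure — each gene dominated by one component
  (SD 0.7 × component scale 1.0/0.85) with cross-loadings at 25% of that.
  Without simple structure an orthogonal rotation of the fitted subspace
  is unidentified and loading recovery is meaningless; real expression
  components exhibit exactly this kind of differentiated gene sets. Ground
  truth stores loadings on the **population correlation scale** (raw
  weights divided by each gene's total spatial SD, including the
  across-donor-median noise contribution, whose variance factor for the
  median of n normals is evaluated once by seeded Monte-Carlo), because
  that is the metric the PCA estimates; at zero noise recovery is then
  exact.
* **Noise**: gene-level spatial noise SD 0.42 and donor replicate noise SD
  0.4, calibrated so the two components jointly explain ≈ 49% of
  standardized variance — the level reported for the real 68 × 8235
  matrix (49.4%). Baseline expression N(6.06, 2²) log2 units; additive
  left-minus-right offset 0.056 (the observed raw hemisphere difference),
  applied before donor noise.
* **Inconsistent genes** (default 50): per donor, independent random
  profiles with no shared spatial structure — the failure mode the
  ρ > 0.446 filter exists to catch.
* **β maps**: mean/SD per measure (0.103/0.034 volume, 0.102/0.027
  surface area, 0.031/0.035 thickness — the reported meta-analytic
  distributions), built from three mutually orthogonalized mirrored
  spatial patterns so the planted couplings are exact in-sample: the
  absolute-score pattern u (couplings −0.5/−0.45/−0.2, signed to emulate
  the reported negative associations), the component-orthogonal specific
  pattern w (weight 0.6), and per-measure residuals. Orthogonalizing the
  patterns removes seed-to-seed leakage between the couplings; mirrored
  construction gives the maps realistic interhemispheric consistency.
* **Specific genes** (default 10): profiles carry 1.0 × w on top of their
  component loadings. These weights were calibrated during design so the
  planted signal is detectable at the default cohort sizes — with the
  emulated effect-map magnitudes the scan operates near the BH threshold,
  which is the realistic sparse-discovery regime.
* **Cohorts**: three, sized 37840/1043/636 with mean ages 63.8/59.3/72.7
  (SD 7.6/10.1/0.4), 4/2/1 sites, test lag only in the narrow-age cohort;
  4/5/13 tests with loadings cycling through (0.75, 0.65, 0.6, 0.5, 0.45);
  test scores λg − 0.3·age_z + 0.1·(sex−½) + residual of unit total
  variance. Regional measures carry their planted standardized β on g plus
  covariate effects (age −0.2, sex 0.3, site shifts ~0.05, small
  head-position and lag effects) and are mapped onto mm³/mm²/mm unit
  scales.
* **Cell types**: 9 named types plus `unclassified`, sizes proportional to
  published single-cell-derived lists (~16.6% of genes classified). A
  planted location shift for one type is implemented by selecting that
  type's genes as the loading-sorted window whose mean sits at the target
  shift.

What the generator does **not** emulate: probe-level microarray structure,
sample-to-region assignment from MNI coordinates, spatial autocorrelation
*within* hemispheres beyond the planted components, non-Gaussian test-score
distributions and their transformations, scanner- or FreeSurfer-version
batch structure, missing cognitive data patterns, and selection effects in
cohort recruitment. Passing recovery tests therefore demonstrate that the
estimators are correct and well-calibrated under the stated model — not
that the scientific conclusions would replicate on real data.

## Numerical and policy choices

* All randomness flows from integer seeds through
  `numpy.random.default_rng`; seed lists (e.g. `[seed, 202, cohort]`)
  fan out stage-level streams without collisions. Same-seed pipeline runs
  are byte-identical, including the output manifest (wall-times are logged,
  not written to artifacts).
* Varimax tolerance 1e-10 / 1000 sweeps; FIML gradient tolerance 1e-6 with
  3 restarts; REML τ² bounded in [0, 10·Var(β)] with xatol 1e-12;
  condition-number guard 1e8; outlier rule strict |z| > 4; BH and Holm via
  statsmodels.
* Degenerate inputs fail loudly with the constraint named (too few
  regions/donors/tests, constant columns, unpaired hemisphere labels,
  mismatched gene universes) except where a degenerate *result* is
  well-defined (all-tied Kruskal-Wallis input → H = 0, p = 1; single-study
  meta → flagged pass-through).
* Problem sizes in the test-suite simulations (e.g. 600-gene atlases for
  unit tests, 500 genes × 20 seeds for error-rate calibration, 100 seeds
  at n = 5000 for loading bias) were chosen as the smallest sizes at which
  the Monte-Carlo error of each check is comfortably below the tolerance
  being asserted.

## Known limitations

* Fit-index formulas under FIML use the EM-saturated model; other software
  may use different small-sample scalings of χ² ((N−1) vs N), which
  changes RMSEA slightly at small n.
* The score-computation convention (standardized projections) reproduces
  score *patterns*, not any particular published score magnitudes;
  analyses consume only scale-free quantities.
* Meta-regression with k = 3 cohorts has a single residual df; its p-values
  are supported by the machinery but carry little information — mirrored in
  the real design being emulated.
* The gene scan's BH control is exact for independent nulls; genes share
  the same β map, and the observed false-discovery proportion in the
  calibration simulations sits slightly above the nominal level while
  remaining within its Monte-Carlo bound.
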