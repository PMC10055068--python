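# cortexg

Spatial components of cortical gene expression and their association with
brain-structure correlates of general cognitive function (*g*).

## The problem

Post-mortem atlases of the human cortex show that thousands of genes share
a small number of spatial expression patterns across regions. `cortexg`
implements, as a tested and reusable pipeline, the analysis that (i)
extracts and validates the two major spatial components of regional gene
expression, and (ii) relates them — and individual genes beyond them — to
meta-analytic maps of how regional brain morphometry (cortical volume,
surface area, thickness) covaries with general cognitive functioning *g*
across multiple population cohorts.

It is written for imaging-transcriptomics and cognitive-neuroscience
researchers who work with region-by-gene expression tables on the
Desikan-Killiany parcellation (34 paired regions per hemisphere) and
subject-level cohort tables of cognitive scores and FreeSurfer regional
morphometry. Because the real cohort data are access-restricted, the
package ships a first-class synthetic-data generator that emulates every
input with known ground truth, so each stage of the pipeline has
parameter-recovery tests.

## The method

1. **Donor-consistency QC** — genes are retained when the mean Spearman
   correlation between each donor's left-hemisphere regional profile and
   the cross-donor median profile exceeds ρ > 0.446; the working matrix is
   the between-donor median expression per (region, gene).
2. **Components** — PCA on the correlation matrix of genes across the 68
   regions (loadings are gene-component correlations in [−1, 1]), varimax
   rotation with Kaiser normalization of the k = 2 retained components,
   deterministic sign-fixing, and z-scaling of the regional component
   scores within each hemisphere (the two hemispheres derive from unequal
   donor counts, which shifts raw expression additively).
3. **Stability** — Tucker's congruence coefficient
   φ(a, b) = Σaᵢbᵢ / √(Σaᵢ²·Σbᵢ²) between solutions: region-subset
   cross-validation (5 partitions of the 68 regions × 50 repeats, PCA refit
   on fold and complement) and matched-gene congruence between solutions
   from different datasets.
4. **Latent g** — per cohort, a single-common-factor model
   xⱼ = μⱼ + λⱼ·g + eⱼ (Var g = 1) estimated by full-information maximum
   likelihood with CFI/TLI/RMSEA/SRMR fit indices and regression-method
   factor scores; tests are first residualized on age and sex.
5. **Meta-analytic mapping** — per region × measure × cohort, a
   standardized β from OLS of the z-scored measure on z-scored g plus
   covariates (age, sex, head position, site, test lag; |z| > 4 outliers
   excluded); inverse-variance random-effects pooling across cohorts
   (τ² by REML, DerSimonian-Laird as an option) for 68 × 3 = 204
   meta-analyses, with mean-age meta-regression and whole-cortex
   adjustment.
6. **Spatial association** — Pearson correlations between regional maps:
   |component score| vs pooled β maps (plus the quadratic-regression
   variant on signed scores), interhemispheric consistency, and
   mean-expression / mean-morphometry controls.
7. **Gene- and cell-type-specific scans** — every gene's hemisphere-scaled
   profile is regressed against each pooled β map controlling both
   component score maps; Benjamini-Hochberg FDR within measure, Q < .05
   sets intersected across measures. Cell-type mean profiles get the same
   regression; loading distributions by cell type are compared with
   Kruskal-Wallis plus Dunn tests vs the unclassified baseline
   (Holm-adjusted).

## Worked example

```python
from cortexg import (SyntheticConfig, generate_expression_atlas,
                     donor_consistency_filter, apply_filter,
                     fit_components, scale_scores_by_hemisphere,
                     region_subset_cv, congruence_matrix)

cfg = SyntheticConfig(seed=42, n_genes=1000)
profiles, matrix, truth = generate_expression_atlas(cfg)

report = donor_consistency_filter(profiles, threshold=0.446)
X = apply_filter(matrix, report)
sol = scale_scores_by_hemisphere(fit_components(X, k=2, rotate=True))
cv = region_subset_cv(X, k=2, n_repeats=10, n_folds=5, seed=0)
cm = congruence_matrix(sol.loadings,
                       truth.planted_loadings.loc[sol.loadings.index])
```

prints (via the obvious `print` statements):

```
retained 952 of 1000 genes (mean donor-to-median rho > 0.446)
unrotated variance: 28.2% / 21.3%
rotated variance:   28.1% / 21.3% (joint 49.5%)
CV congruence: C1: 0.923 (SD 0.017), C2: 0.896 (SD 0.024)
estimated C1 matches planted T1: |phi| = 0.988
estimated C2 matches planted T2: |phi| = 0.982
```

Reading: the QC dropped essentially all of the 48 planted
donor-inconsistent genes; the two rotated components jointly carry ~50% of
the standardized regional variance; refitting the PCA on random region
subsets reproduces the loading patterns at mean |φ| ≈ 0.90-0.92; and the
estimated loadings recover the planted spatial components at |φ| ≈ 0.99.

The full chain — cohort simulation, latent-g models, 204 random-effects
meta-analyses, spatial associations and the gene/cell-type scans — runs
from one config:

```bash
cortexg run-all --out runs/demo --seed 1          # writes manifest.json
cortexg simulate --out sim --seed 1               # individual stages
cortexg qc --profiles sim/donor_profiles.tsv --threshold 0.446
cortexg components --expression expression_filtered.tsv --k 2
```

Every artifact is a headered TSV/CSV or JSON; `manifest.json` lists each
file with a content hash, and two runs with the same seed are
byte-identical.

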