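"""Synthetic donor atlases, cohorts and cell-type maps with known ground truth.

The generator emulates the structures the analysis consumes, so every
downstream stage has a parameter-recovery test:

* a low-rank region-by-gene expression matrix with two planted orthogonal
  spatial components, mirrored across hemispheres (interhemispheric score
  correlation ~0.8), gene-level spatial noise, an additive left-minus-right
  mean offset emulating the unequal-donor-count artifact of the source
  atlas, donor-level replicate noise, and a subset of "inconsistent" genes
  whose donor profiles are independent noise;
* multi-cohort subject tables in which test scores follow a
  single-common-factor model of g and regional morphometry carries planted
  standardized g-associations whose spatial profile is coupled to the
  absolute planted component scores;
* a small set of "specific" genes whose profiles track a g-beta spatial
  pattern orthogonal to the planted components.

No generative model for these data exists in the literature; all
distributional choices here are explicit stand-ins chosen to be realistic
for log2-scale microarray summaries and population cohort tables (see the
methods note).  Identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import hemisphere_of, region_labels

UNCLASSIFIED_LABEL = "unclassified"

CELL_TYPES = (
    "astrocytes", "ca1_pyramidal", "endothelial", "ependymal", "interneurons",
    "microglia", "mural", "oligodendrocytes", "s1_pyramidal",
)
#: Classified-gene share per cell type, proportional to published
#: mouse-cortex-derived lists matched into a human cortical gene set.
CELL_TYPE_WEIGHTS = (129, 204, 127, 191, 181, 185, 60, 139, 155)

MEASURES = ("volume", "surface_area", "thickness")

# Cohort demography emulating three adult population cohorts: one large
# biobank-scale sample and two smaller samples, one with a very narrow
# age range.  Mean ages differ so age moderation is testable.
COHORT_AGE_MEAN = (63.8, 59.3, 72.7)
COHORT_AGE_SD = (7.6, 10.1, 0.4)
COHORT_N_SITES = (4, 2, 1)

# Region-level morphometry units (means/SDs used to map standardized
# effects onto mm^3 / mm^2 / mm scales).
MEASURE_UNIT_MEAN = {"volume": 5500.0, "surface_area": 2300.0, "thickness": 2.55}
MEASURE_UNIT_SD = {"volume": 600.0, "surface_area": 250.0, "thickness": 0.12}

# Planted pooled-beta map levels: mean and spatial SD per measure, and the
# coupling of the map to the absolute planted component scores.
BETA_MEAN = {"volume": 0.103, "surface_area": 0.102, "thickness": 0.031}
BETA_SD = {"volume": 0.034, "surface_area": 0.027, "thickness": 0.035}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults are the emulated study conditions."""

    n_regions_per_hemisphere: int = 34
    n_genes: int = 2000
    n_components: int = 2
    loading_scale: float = 0.7
    component_scale: tuple = (1.0, 0.85)  # relative strength per component
    cross_loading: float = 0.25          # off-axis loading fraction (simple structure)
    noise_sd: float = 0.42
    hemisphere_offset: float = 0.056     # left-minus-right mean shift, log2 units
    mirror_correlation: float = 0.8      # interhemispheric planted-score correlation
    baseline_mean: float = 6.06          # gene baseline expression, log2 units
    baseline_sd: float = 2.0
    n_donors: int = 6
    donor_noise_sd: float = 0.4
    n_inconsistent_genes: int = 50
    n_cohorts: int = 3
    n_subjects: tuple = (37840, 1043, 636)
    n_tests: tuple | int = (4, 5, 13)
    g_loadings: tuple = (0.75, 0.65, 0.6, 0.5, 0.45)
    age_effect: float = -0.3             # standardized age effect on test scores
    sex_effect: float = 0.1
    beta_coupling: tuple = (-0.5, -0.45, -0.2)   # |score| coupling per measure
    specific_coupling: float = 0.6       # beta-map weight on the specific pattern
    n_specific_genes: int = 10
    specific_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_regions_per_hemisphere": self.n_regions_per_hemisphere,
            "n_genes": self.n_genes, "n_components": self.n_components,
            "n_donors": self.n_donors, "n_cohorts": self.n_cohorts,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        for name in ("n_inconsistent_genes", "n_specific_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("noise_sd", "donor_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if 2 * self.n_regions_per_hemisphere < self.n_components:
            raise ValueError(
                "degenerate config: total regions "
                f"({2 * self.n_regions_per_hemisphere}) < n_components "
                f"({self.n_components})"
            )
        if self.n_inconsistent_genes + self.n_specific_genes > self.n_genes:
            raise ValueError("inconsistent + specific genes exceed n_genes")
        if not all(0 < l < 1 for l in self.g_loadings):
            raise ValueError("g_loadings must lie in (0, 1)")
        if isinstance(self.n_subjects, int):
            self.n_subjects = (self.n_subjects,) * self.n_cohorts
        if len(self.n_subjects) != self.n_cohorts:
            raise ValueError("n_subjects must have one entry per cohort")
        if isinstance(self.n_tests, int):
            self.n_tests = (self.n_tests,) * self.n_cohorts

    def tests_for(self, cohort_index: int) -> int:
        return self.n_tests[cohort_index % len(self.n_tests)]


@dataclass
class GroundTruth:
    planted_loadings: pd.DataFrame       # gene x component, correlation metric
    planted_weights: pd.DataFrame        # gene x component, raw generative weights
    planted_scores: pd.DataFrame         # region x component (orthogonal columns)
    planted_beta_maps: pd.DataFrame      # region x measure
    specific_gene_ids: list
    specific_pattern: pd.Series          # component-orthogonal spatial pattern
    inconsistent_gene_ids: list
    subject_g: dict = field(default_factory=dict)   # cohort -> per-subject g
    cohort_loadings: dict = field(default_factory=dict)


def _median_noise_var_factor(n_donors: int) -> float:
    """Variance of the median of ``n_donors`` standard normals.

    Evaluated once by seeded Monte Carlo (deterministic); used to express
    the planted loadings on the population correlation scale, where the
    across-donor median of replicate noise contributes this factor times
    the donor noise variance to each gene's residual spatial variance.
    """
    if n_donors == 1:
        return 1.0
    rng = np.random.default_rng(918273645)
    draws = rng.standard_normal((200_000, n_donors))
    return float(np.median(draws, axis=1).var())


def _orthonormal_centered(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k centered, mutually orthogonal columns with population variance 1."""
    G = rng.standard_normal((n, max(2 * k, k + 1)))
    G -= G.mean(axis=0)
    Q, _ = np.linalg.qr(G)
    return Q[:, :k] * np.sqrt(n)


def _planted_scores(rng: np.random.Generator, n_per_hemi: int, k: int,
                    mirror_r: float) -> np.ndarray:
    """Planted score matrix: orthogonal columns, unit variance per hemisphere,
    with left/right patterns correlated at ``mirror_r``."""
    basis = _orthonormal_centered(rng, n_per_hemi, 2 * k)
    L = basis[:, :k]
    E = basis[:, k:]
    R = mirror_r * L + np.sqrt(1.0 - mirror_r ** 2) * E
    return np.vstack([L, R])


def generate_expression_atlas(config: SyntheticConfig):
    """Donor-level profiles, their median summary matrix, and the ground truth.

    Returns ``(DonorProfiles, ExpressionMatrix, GroundTruth)`` where the
    profiles are a long-format table and the matrix is regions x genes.
    """
    from .expression_qc import DonorProfiles

    rng = np.random.default_rng([config.seed, 101])
    regions = region_labels(config.n_regions_per_hemisphere)
    n_regions = len(regions)
    genes = [f"GENE{i:05d}" for i in range(config.n_genes)]
    k = config.n_components

    S = _planted_scores(rng, config.n_regions_per_hemisphere, k,
                        config.mirror_correlation)
    # simple-structure loadings: each gene tracks mainly one spatial
    # component, with a small cross-loading — the configuration under
    # which an orthogonal rotation of the fitted subspace is identifiable
    comp_sd = config.loading_scale * np.array(
        [config.component_scale[i % len(config.component_scale)] for i in range(k)])
    dominant = rng.integers(0, k, size=config.n_genes)
    sd_matrix = np.where(
        dominant[:, None] == np.arange(k)[None, :],
        comp_sd[None, :], config.cross_loading * comp_sd[None, :])
    A = rng.standard_normal((config.n_genes, k)) * sd_matrix
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)

    # choose the special gene subsets disjointly
    order = rng.permutation(config.n_genes)
    inconsistent_idx = np.sort(order[:config.n_inconsistent_genes])
    specific_idx = np.sort(order[config.n_inconsistent_genes:
                                 config.n_inconsistent_genes + config.n_specific_genes])

    def mirrored_pattern(orthogonal_to=None):
        """Spatial pattern mirrored across hemispheres (corr = mirror
        correlation), like real cortical maps; optionally residualized
        against the planted score columns."""
        half = rng.standard_normal((config.n_regions_per_hemisphere, 2))
        half -= half.mean(axis=0)
        rho = config.mirror_correlation
        raw = np.concatenate([half[:, 0], rho * half[:, 0]
                              + np.sqrt(1 - rho ** 2) * half[:, 1]])
        raw -= raw.mean()
        if orthogonal_to is not None:
            raw = raw - orthogonal_to @ np.linalg.lstsq(orthogonal_to, raw,
                                                        rcond=None)[0]
        return raw / raw.std()

    # the beta maps are built from mutually orthogonal spatial patterns so
    # the planted couplings are exact in-sample: u (the mirrored absolute-
    # score pattern), w (the component-orthogonal pattern the specific
    # genes track) and per-measure residual patterns eta
    abs_mix = np.abs(S).mean(axis=1)
    u = (abs_mix - abs_mix.mean()) / abs_mix.std()
    w = mirrored_pattern(orthogonal_to=np.column_stack([S, u]))

    X = baseline[None, :] + S @ A.T
    if config.n_specific_genes:
        X[:, specific_idx] += config.specific_effect * w[:, None]
    X += rng.normal(0.0, config.noise_sd, size=X.shape)

    hemis = hemisphere_of(regions)
    offset = np.where(hemis == "L", config.hemisphere_offset / 2,
                      -config.hemisphere_offset / 2)
    X += offset[:, None]

    frames = []
    for d in range(config.n_donors):
        Xd = X + rng.normal(0.0, config.donor_noise_sd, size=X.shape)
        if config.n_inconsistent_genes:
            # independent donor-specific profiles: no shared spatial structure
            Xd[:, inconsistent_idx] = (
                baseline[inconsistent_idx][None, :]
                + rng.normal(0.0, 1.0, size=(n_regions, len(inconsistent_idx)))
            )
        frames.append(pd.DataFrame({
            "donor": f"donor{d + 1}",
            "region": np.repeat(regions, config.n_genes),
            "gene": np.tile(genes, n_regions),
            "value": Xd.ravel(),
        }))
    profiles = DonorProfiles(pd.concat(frames, ignore_index=True))

    donor_stack = np.stack([
        frames[d]["value"].to_numpy().reshape(n_regions, config.n_genes)
        for d in range(config.n_donors)
    ])
    summary = pd.DataFrame(np.median(donor_stack, axis=0), index=pd.Index(regions, name="region"),
                           columns=pd.Index(genes, name="gene"))

    comp_names = [f"T{i + 1}" for i in range(k)]
    couplings = np.array([config.beta_coupling[i % len(config.beta_coupling)]
                          for i in range(len(MEASURES))])
    base_patterns = np.column_stack([S, u, w])
    beta_maps = {}
    for i, m in enumerate(MEASURES):
        c = couplings[i]
        d = config.specific_coupling
        resid_w = np.sqrt(max(0.0, 1.0 - c ** 2 - d ** 2))
        eta = mirrored_pattern(orthogonal_to=base_patterns)
        beta_maps[m] = BETA_MEAN[m] + BETA_SD[m] * (c * u + d * w + resid_w * eta)
    # planted loadings on the correlation scale the PCA estimates:
    # corr(gene profile, S_j) = A_gj / sqrt(signal + residual spatial var)
    resid_var = (config.noise_sd ** 2
                 + _median_noise_var_factor(config.n_donors) * config.donor_noise_sd ** 2)
    signal_var = (A ** 2).sum(axis=1)
    if config.n_specific_genes:
        signal_var[specific_idx] += config.specific_effect ** 2
    denom = np.sqrt(np.maximum(signal_var + resid_var, 1e-30))
    A_corr = A / denom[:, None]
    truth = GroundTruth(
        planted_loadings=pd.DataFrame(A_corr, index=summary.columns, columns=comp_names),
        planted_weights=pd.DataFrame(A, index=summary.columns, columns=comp_names),
        planted_scores=pd.DataFrame(S, index=summary.index, columns=comp_names),
        planted_beta_maps=pd.DataFrame(beta_maps, index=summary.index),
        specific_gene_ids=[genes[i] for i in specific_idx],
        specific_pattern=pd.Series(w, index=summary.index, name="specific_pattern"),
        inconsistent_gene_ids=[genes[i] for i in inconsistent_idx],
    )
    return profiles, summary, truth


def generate_cohort(config: SyntheticConfig, truth: GroundTruth,
                    cohort_index: int, residual_scale: float = 1.0) -> pd.DataFrame:
    """One cohort's subject table: tests, covariates and regional morphometry.

    Test scores follow ``lambda * g + age/sex effects + residual`` with
    residual variance ``residual_scale * (1 - lambda^2)`` so that at the
    default scale the tests have unit variance.  Each regional measure
    carries its planted standardized g-association plus covariate effects,
    mapped onto physical units.  The drawn per-subject g is recorded in
    ``truth.subject_g[cohort_index]``.
    """
    if cohort_index >= config.n_cohorts:
        raise ValueError(f"cohort_index {cohort_index} >= n_cohorts {config.n_cohorts}")
    rng = np.random.default_rng([config.seed, 202, cohort_index])
    n = config.n_subjects[cohort_index]
    p_tests = config.tests_for(cohort_index)
    lam = np.array([config.g_loadings[i % len(config.g_loadings)]
                    for i in range(p_tests)])

    g = rng.standard_normal(n)
    age_mu = COHORT_AGE_MEAN[cohort_index % len(COHORT_AGE_MEAN)]
    age_sd = COHORT_AGE_SD[cohort_index % len(COHORT_AGE_SD)]
    age = rng.normal(age_mu, age_sd, size=n)
    age_z = (age - age.mean()) / age.std()
    sex = rng.integers(0, 2, size=n)
    n_sites = COHORT_N_SITES[cohort_index % len(COHORT_N_SITES)]
    site = rng.integers(0, n_sites, size=n)
    head = rng.normal(0.0, 5.0, size=(n, 3))
    lag = rng.normal(65.0, 38.0, size=n) if age_sd < 1 else np.zeros(n)

    table = pd.DataFrame({
        "subject": [f"c{cohort_index}_s{i:06d}" for i in range(n)],
        "age": age, "sex": sex, "site": [f"site{s}" for s in site],
        "head_x": head[:, 0], "head_y": head[:, 1], "head_z": head[:, 2],
        "lag": lag,
    }).set_index("subject")

    new_cols = {}
    for j in range(p_tests):
        resid_var = residual_scale * (1.0 - lam[j] ** 2)
        eps = rng.standard_normal(n) * np.sqrt(resid_var)
        new_cols[f"test{j + 1}"] = (lam[j] * g + config.age_effect * age_z
                                    + config.sex_effect * (sex - 0.5) + eps)

    site_shift = rng.normal(0.0, 0.05, size=n_sites)
    head_eff = np.array([0.02, -0.02, 0.02])
    lag_z = (lag - lag.mean()) / (lag.std() + 1e-12)
    for m in MEASURES:
        betas = truth.planted_beta_maps[m]
        for region, b in betas.items():
            struct = (b * g - 0.2 * age_z + 0.3 * (sex - 0.5)
                      + site_shift[site] + head @ head_eff + 0.01 * lag_z)
            var_struct = b ** 2 + 0.2 ** 2 + 0.3 ** 2 * 0.25 + 0.05 ** 2 + (head_eff ** 2 * 25).sum()
            eps_sd = np.sqrt(max(0.05, 1.0 - var_struct))
            z = struct + rng.standard_normal(n) * eps_sd
            new_cols[f"{region}__{m}"] = MEASURE_UNIT_MEAN[m] + MEASURE_UNIT_SD[m] * z
    table = pd.concat([table, pd.DataFrame(new_cols, index=table.index)], axis=1)

    truth.subject_g[cohort_index] = pd.Series(g, index=table.index, name="g")
    truth.cohort_loadings[cohort_index] = pd.Series(
        lam, index=[f"test{j + 1}" for j in range(p_tests)], name="lambda")
    return table


def generate_celltype_map(config: SyntheticConfig, truth: GroundTruth,
                          shift_type: str | None = None, shift: float = 0.0,
                          n_per_type: int | None = None,
                          component: str | None = None,
                          seed_offset: int = 0) -> pd.Series:
    """Assign genes to 9 named cell types plus an 'unclassified' baseline.

    With ``shift_type`` set, that type's genes are chosen (by a sliding
    window over loading-sorted genes) so their mean planted loading on
    ``component`` (default: first) sits ``shift`` above the overall mean —
    a planted location shift for the distribution tests.  All other types
    are random draws from the remaining pool.
    """
    genes = truth.planted_loadings.index
    n_genes = len(genes)
    rng = np.random.default_rng([config.seed, 303, seed_offset])
    weights = np.array(CELL_TYPE_WEIGHTS, dtype=float)
    if n_per_type is None:
        counts = np.maximum(2, np.round(weights / weights.sum()
                                        * 0.166 * n_genes).astype(int))
    else:
        counts = np.full(len(CELL_TYPES), int(n_per_type))
    if counts.sum() > n_genes:
        raise ValueError("cell-type counts exceed the gene universe")

    assignment = pd.Series(UNCLASSIFIED_LABEL, index=genes, dtype=object)
    available = np.arange(n_genes)
    if shift_type is not None:
        if shift_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {shift_type!r}")
        comp = component or truth.planted_loadings.columns[0]
        load = truth.planted_loadings[comp].to_numpy()
        m = counts[CELL_TYPES.index(shift_type)]
        target = load.mean() + shift
        order = np.argsort(load)
        sorted_load = load[order]
        csum = np.concatenate([[0.0], np.cumsum(sorted_load)])
        window_means = (csum[m:] - csum[:-m]) / m
        start = int(np.argmin(np.abs(window_means - target)))
        chosen = order[start:start + m]
        assignment.iloc[chosen] = shift_type
        available = np.setdiff1d(available, chosen)
    for ct, m in zip(CELL_TYPES, counts):
        if ct == shift_type:
            continue
        pick = rng.choice(available, size=m, replace=False)
        assignment.iloc[pick] = ct
        available = np.setdiff1d(available, pick)
    assignment.name = "cell_type"
    return assignment
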