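"""Per-region g-morphometry effects and random-effects meta-analysis.

For each cohort, each of the 68 regions and each morphometry measure
(volume, surface area, thickness), a standardized beta is estimated by
OLS of the z-scored regional measure on z-scored g plus covariates (age,
sex, scanner head position, testing site, test lag).  The per-cohort
betas are then pooled across cohorts with an inverse-variance
random-effects model (68 regions x 3 measures = 204 meta-analyses when
all regions and measures are present), with between-cohort heterogeneity
tau^2 estimated by REML (default) or DerSimonian-Laird.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

MEASURES = ("volume", "surface_area", "thickness")


def exclude_outliers(values: np.ndarray | pd.Series, sd_cut: float = 4.0):
    """Drop values strictly more than ``sd_cut`` SDs from the mean.

    Returns (mask of retained entries, number excluded).  A value at
    exactly ``sd_cut`` SDs is retained (strict inequality).  Zero-SD
    input yields no exclusions with a warning.
    """
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 10:
        raise ValueError("need at least 10 values for outlier screening")
    sd = v[ok].std()
    if sd == 0:
        warnings.warn("zero SD: no outlier exclusions possible")
        return ok, 0
    z = np.abs(v - v[ok].mean()) / sd
    keep = ok & ~(z > sd_cut)
    return keep, int(ok.sum() - keep.sum())


@dataclass
class EffectEstimate:
    region: str
    measure: str
    cohort: str
    beta: float
    se: float
    n: int
    n_excluded: int = 0
    flags: tuple = ()


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def build_covariate_design(covariates: pd.DataFrame | None,
                           categorical: tuple[str, ...] = ("site",)) -> np.ndarray | None:
    """Numeric design columns for nuisance covariates.

    Categorical columns become indicator contrasts with the largest level
    as reference; numeric columns are centered (centering does not affect
    the g coefficient but keeps the design well-conditioned).
    """
    if covariates is None or covariates.shape[1] == 0:
        return None
    cols = []
    for c in covariates.columns:
        col = covariates[c]
        if c in categorical or col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            counts = col.value_counts()
            ref = counts.index[0]
            for level in counts.index[1:]:
                cols.append((col == level).to_numpy(dtype=float))
        else:
            x = col.to_numpy(dtype=float)
            cols.append(x - np.nanmean(x))
    if not cols:
        return None
    return np.column_stack(cols)


def standardized_beta(g, measure, covariates: pd.DataFrame | None = None,
                      region: str = "", measure_name: str = "", cohort: str = "",
                      sd_cut: float | None = 4.0) -> EffectEstimate:
    """Standardized association between g and one regional measure.

    Outlying measure values (|z| > sd_cut, strict) are excluded first;
    both g and the measure are then z-scored on the analysis sample, so
    the reported coefficient is a standardized beta.  Collinear covariate
    columns are dropped with a warning.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(measure, dtype=float)
    C = build_covariate_design(covariates)
    ok = ~np.isnan(g) & ~np.isnan(y)
    if C is not None:
        ok &= ~np.isnan(C).any(axis=1)
    n_excluded = 0
    if sd_cut is not None and ok.sum() >= 10:
        keep, n_excluded = exclude_outliers(np.where(ok, y, np.nan), sd_cut)
        ok &= keep
    n = int(ok.sum())
    p_cov = 0 if C is None else C.shape[1]
    if n < p_cov + 3:
        raise ValueError(f"only {n} complete cases for {p_cov} covariates")
    gz = _zscore(g[ok])
    yz = _zscore(y[ok])
    design = [np.ones(n), gz]
    flags = []
    if C is not None:
        Cok = C[ok]
        base = np.column_stack(design)
        for j in range(Cok.shape[1]):
            cand = np.column_stack([base, Cok[:, j]])
            if np.linalg.matrix_rank(cand) == cand.shape[1]:
                base = cand
            else:
                flags.append(f"dropped_collinear_covariate_{j}")
                warnings.warn(f"dropping collinear covariate column {j}")
        design_mat = base
    else:
        design_mat = np.column_stack(design)
    beta_hat, _, _, _ = np.linalg.lstsq(design_mat, yz, rcond=None)
    resid = yz - design_mat @ beta_hat
    dof = n - design_mat.shape[1]
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(design_mat.T @ design_mat)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    b = float(beta_hat[1])
    if abs(b) >= 1:
        flags.append("implausible_beta")
    return EffectEstimate(region=region, measure=measure_name, cohort=cohort,
                          beta=b, se=se, n=n, n_excluded=n_excluded,
                          flags=tuple(flags))


# ---------------------------------------------------------------------------
# random-effects pooling


def _dl_tau2(beta: np.ndarray, var: np.ndarray) -> tuple[float, float]:
    """DerSimonian-Laird tau^2 and Cochran's Q."""
    w = 1.0 / var
    bfe = (w * beta).sum() / w.sum()
    q = (w * (beta - bfe) ** 2).sum()
    df = len(beta) - 1
    c = w.sum() - (w ** 2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / c)
    return tau2, float(q)


def _reml_tau2(beta: np.ndarray, var: np.ndarray) -> float:
    """REML estimate of tau^2 for the intercept-only random-effects model."""

    def neg_restricted_ll(tau2):
        v = var + tau2
        w = 1.0 / v
        bhat = (w * beta).sum() / w.sum()
        return 0.5 * (np.log(v).sum() + np.log(w.sum())
                      + (w * (beta - bhat) ** 2).sum())

    hi = max(1e-6, 10.0 * beta.var())
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(0.0, hi), method="bounded",
                                   options={"xatol": 1e-12})
    return float(max(0.0, res.x))


@dataclass
class MetaResult:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q: float
    p: float
    k: int
    method: str
    flags: tuple = ()


def random_effects_meta(betas, ses, method: str = "reml") -> MetaResult:
    """Inverse-variance random-effects pooling of k study effects.

    ``method`` selects the tau^2 estimator: 'reml' (default) or 'dl'
    (DerSimonian-Laird closed form).  With k = 1 the single estimate is
    passed through, flagged.
    """
    beta = np.asarray(betas, dtype=float)
    var = np.asarray(ses, dtype=float) ** 2
    k = len(beta)
    if k == 1:
        se = float(np.sqrt(var[0]))
        p = 2 * stats.norm.sf(abs(beta[0]) / se)
        return MetaResult(float(beta[0]), se, float(beta[0] - 1.959963984540054 * se),
                          float(beta[0] + 1.959963984540054 * se), 0.0, 0.0, float(p),
                          1, method, flags=("single_study",))
    tau2_dl, q = _dl_tau2(beta, var)
    if method == "dl":
        tau2 = tau2_dl
    elif method == "reml":
        tau2 = _reml_tau2(beta, var)
    else:
        raise ValueError(f"unknown tau^2 method {method!r}")
    w = 1.0 / (var + tau2)
    pooled = float((w * beta).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    zcrit = 1.959963984540054
    p = float(2 * stats.norm.sf(abs(pooled) / se))
    return MetaResult(pooled, se, pooled - zcrit * se, pooled + zcrit * se,
                      float(tau2), q, p, k, method)


def meta_effect_map(estimates: list[EffectEstimate], method: str = "reml") -> pd.DataFrame:
    """Pool per-cohort effect estimates into one row per (region, measure)."""
    df = pd.DataFrame([e.__dict__ for e in estimates])
    rows = []
    for (region, measure), grp in df.groupby(["region", "measure"], sort=True):
        res = random_effects_meta(grp["beta"].to_numpy(), grp["se"].to_numpy(), method)
        rows.append({"region": region, "measure": measure, "beta": res.beta,
                     "se": res.se, "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "tau2": res.tau2, "Q": res.q, "p": res.p, "k": res.k})
    return pd.DataFrame(rows)


def moderator_meta_regression(betas, ses, moderator, method: str = "reml") -> dict:
    """Mixed-effects meta-regression of study effects on one moderator.

    Requires k >= 3 for a testable slope (k = 2 leaves 0 residual df and
    is returned flagged).  Slope SE and two-sided p are Wald-type.
    """
    beta = np.asarray(betas, dtype=float)
    var = np.asarray(ses, dtype=float) ** 2
    x = np.asarray(moderator, dtype=float)
    k = len(beta)
    if np.ptp(x) == 0:
        raise ValueError("moderator is constant across studies")
    if k < 3:
        return {"slope": np.nan, "se": np.nan, "p": np.nan, "tau2": np.nan,
                "k": k, "testable": False}
    X = np.column_stack([np.ones(k), x - x.mean()])

    def neg_restricted_ll(tau2):
        v = var + tau2
        W = np.diag(1.0 / v)
        xtwx = X.T @ W @ X
        b = np.linalg.solve(xtwx, X.T @ W @ beta)
        r = beta - X @ b
        sign, logdet = np.linalg.slogdet(xtwx)
        return 0.5 * (np.log(v).sum() + logdet + r @ W @ r)

    hi = max(1e-6, 10.0 * beta.var())
    if method == "reml":
        res = optimize.minimize_scalar(neg_restricted_ll, bounds=(0.0, hi),
                                       method="bounded", options={"xatol": 1e-12})
        tau2 = float(max(0.0, res.x))
    else:  # method-of-moments fallback on residual Q
        b0, *_ = np.linalg.lstsq(np.diag(1 / np.sqrt(var)) @ X,
                                 beta / np.sqrt(var), rcond=None)
        r = beta - X @ b0
        q = (r ** 2 / var).sum()
        w = 1 / var
        c = w.sum() - (w ** 2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 2)) / c)
    v = var + tau2
    W = np.diag(1.0 / v)
    cov = np.linalg.inv(X.T @ W @ X)
    b = cov @ X.T @ W @ beta
    se = float(np.sqrt(cov[1, 1]))
    slope = float(b[1])
    p = float(2 * stats.norm.sf(abs(slope) / se))
    return {"slope": slope, "se": se, "p": p, "tau2": tau2, "k": k, "testable": True}


def whole_cortex_adjustment(cohort_tables: dict[str, pd.DataFrame],
                            g_scores: dict[str, pd.Series],
                            region_columns: dict[str, list[str]],
                            covariate_columns: dict[str, list[str]],
                            method: str = "reml") -> dict:
    """Re-estimate regional g-associations controlling the whole-cortex measure.

    The total is the across-region sum for volume and surface area and the
    across-region mean for thickness.  Returns the g-association of each
    total, the adjusted pooled map, and the Pearson correlation between
    the adjusted and unadjusted pooled regional profiles per measure.
    """
    from .spatial_assoc import map_correlation

    total_assoc = {}
    adjusted_estimates: list[EffectEstimate] = []
    unadjusted_estimates: list[EffectEstimate] = []
    for cohort, table in cohort_tables.items():
        g = g_scores[cohort].to_numpy()
        covars = table[covariate_columns[cohort]] if covariate_columns[cohort] else None
        for measure in MEASURES:
            cols = [c for c in region_columns[measure] if c in table.columns]
            block = table[cols].to_numpy(dtype=float)
            total = block.sum(axis=1) if measure != "thickness" else block.mean(axis=1)
            est_total = standardized_beta(g, total, covars, region="whole_cortex",
                                          measure_name=measure, cohort=cohort,
                                          sd_cut=None)
            total_assoc.setdefault(measure, []).append(est_total)
            cov_plus = (covars.copy() if covars is not None
                        else pd.DataFrame(index=table.index))
            cov_plus["_total"] = total
            for col in cols:
                region = col.split("__")[0]
                unadjusted_estimates.append(standardized_beta(
                    g, table[col], covars, region=region,
                    measure_name=measure, cohort=cohort))
                adjusted_estimates.append(standardized_beta(
                    g, table[col], cov_plus, region=region,
                    measure_name=measure, cohort=cohort))
    adj_map = meta_effect_map(adjusted_estimates, method)
    unadj_map = meta_effect_map(unadjusted_estimates, method)
    profile_corr = {}
    for measure in MEASURES:
        a = adj_map[adj_map.measure == measure].set_index("region")["beta"]
        u = unadj_map[unadj_map.measure == measure].set_index("region")["beta"]
        profile_corr[measure] = map_correlation(a, u).r
    total_pooled = {
        m: random_effects_meta([e.beta for e in ests], [e.se for e in ests], method)
        for m, ests in total_assoc.items()
    }
    return {"total_associations": total_pooled, "adjusted_map": adj_map,
            "unadjusted_map": unadj_map, "profile_correlations": profile_corr}
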