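"""Gene- and cell-type-specific associations beyond the general components.

After hemisphere-wise scaling of each gene's regional profile, every gene
is regressed against a pooled g-beta map while controlling for the two
general component score maps; the gene coefficient therefore captures
spatial signal specific to that gene, beyond the shared dimensions of
cortical expression.  BH FDR is applied within each morphometry measure
and the Q < .05 sets are intersected across measures.  Cell-type analyses
run the same profile regression on the mean profile of each cell type's
genes, and compare loading distributions across cell types with a
Kruskal-Wallis test plus Dunn post-hoc comparisons (Holm-adjusted)
against the unclassified baseline group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import hemisphere_of

UNCLASSIFIED = "unclassified"
COLLINEARITY_CONDITION_LIMIT = 1e8


def hemisphere_scale_genes(X: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-standardize each gene within each hemisphere across regions.

    Removes additive hemisphere offsets from every gene profile.  Genes
    constant within a hemisphere cannot be scaled and are dropped (their
    names are available on the result as ``.attrs['excluded_genes']``).
    """
    hemis = hemisphere_of(X.index)
    out = X.copy().astype(float)
    bad: set = set()
    for h in np.unique(hemis):
        block = X.loc[hemis == h]
        sd = block.std(ddof=ddof)
        bad |= set(sd.index[(sd == 0) | sd.isna()])
        out.loc[hemis == h] = (block - block.mean()) / sd
    if bad:
        out = out.drop(columns=sorted(bad))
    out.attrs["excluded_genes"] = sorted(bad)
    return out


def gene_profile_regression(gene_profile: pd.Series, beta_map: pd.Series,
                            component_scores: pd.DataFrame) -> dict:
    """OLS of a beta map on one gene profile plus the component scores.

    Returns the gene coefficient, its SE and two-sided p.  Near-perfect
    collinearity of the gene with the control scores (design condition
    number above 1e8) sets ``unstable=True`` instead of failing.
    """
    idx = beta_map.index.intersection(gene_profile.index).intersection(component_scores.index)
    y = beta_map.loc[idx].to_numpy(dtype=float)
    x = gene_profile.loc[idx].to_numpy(dtype=float)
    S = component_scores.loc[idx].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(idx)), x, S])
    unstable = bool(np.linalg.cond(X) > COLLINEARITY_CONDITION_LIMIT)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(idx) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(cov[1, 1]))
    t = coef[1] / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), dof))
    return {"beta": float(coef[1]), "se": se, "p": p, "n": int(len(idx)),
            "unstable": unstable}


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (Q)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GeneAssociationTable:
    measure: str
    table: pd.DataFrame       # gene x (beta, se, p, q, significant, unstable)
    alpha: float = 0.05

    @property
    def significant_genes(self) -> set:
        return set(self.table.index[self.table["significant"]])


def gene_association_scan(X_scaled: pd.DataFrame, beta_maps: pd.DataFrame,
                          component_scores: pd.DataFrame,
                          alpha: float = 0.05) -> dict[str, GeneAssociationTable]:
    """Per-gene component-controlled profile regressions for every measure.

    ``X_scaled`` must already be hemisphere-scaled.  FDR is run separately
    within each measure, then intersected by the caller.
    """
    idx = X_scaled.index.intersection(beta_maps.index).intersection(component_scores.index)
    Xv = X_scaled.loc[idx].to_numpy(dtype=float)
    S = component_scores.loc[idx].to_numpy(dtype=float)
    n = len(idx)
    base = np.column_stack([np.ones(n), S])
    out = {}
    for measure in beta_maps.columns:
        y = beta_maps.loc[idx, measure].to_numpy(dtype=float)
        rows = np.empty((Xv.shape[1], 3))
        unstable = np.zeros(Xv.shape[1], dtype=bool)
        for j in range(Xv.shape[1]):
            X = np.column_stack([np.ones(n), Xv[:, j], S])
            unstable[j] = np.linalg.cond(X) > COLLINEARITY_CONDITION_LIMIT
            coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            dof = n - X.shape[1]
            sigma2 = resid @ resid / dof
            se = np.sqrt(sigma2 * np.linalg.pinv(X.T @ X)[1, 1])
            t = coef[1] / se if se > 0 else np.inf
            rows[j] = (coef[1], se, 2 * stats.t.sf(abs(t), dof))
        tab = pd.DataFrame(rows, index=X_scaled.columns, columns=["beta", "se", "p"])
        tab["q"] = bh_fdr(tab["p"])
        tab["significant"] = tab["q"] < alpha
        tab["unstable"] = unstable
        out[measure] = GeneAssociationTable(measure=measure, table=tab, alpha=alpha)
    _ = base
    return out


def cross_measure_intersection(tables: dict[str, GeneAssociationTable]) -> dict:
    """Pairwise and all-measure intersections of the FDR-significant sets."""
    universes = {m: set(t.table.index) for m, t in tables.items()}
    first = next(iter(universes.values()))
    if any(u != first for u in universes.values()):
        raise ValueError("gene universes differ between measures")
    sig = {m: t.significant_genes for m, t in tables.items()}
    measures = list(tables)
    pairwise = {}
    for i, a in enumerate(measures):
        for b in measures[i + 1:]:
            pairwise[(a, b)] = sig[a] & sig[b]
    allm = set(first)
    for s in sig.values():
        allm &= s
    return {
        "per_measure_counts": {m: len(s) for m, s in sig.items()},
        "pairwise": pairwise,
        "pairwise_counts": {k: len(v) for k, v in pairwise.items()},
        "all_measures": allm,
        "n_all_measures": len(allm),
    }


# ---------------------------------------------------------------------------
# cell types


def celltype_profile_regression(celltype_map: pd.Series, X: pd.DataFrame,
                                beta_maps: pd.DataFrame,
                                component_scores: pd.DataFrame,
                                alpha: float = 0.05,
                                baseline: str = UNCLASSIFIED) -> pd.DataFrame:
    """Component-controlled profile regression for each cell type's mean profile.

    For each cell type (baseline group excluded) the mean regional profile
    over its genes is hemisphere-scaled and regressed on each beta map
    controlling the component scores; BH FDR runs across the
    (type x measure) grid.
    """
    types = [t for t in celltype_map.unique() if t != baseline]
    rows = []
    for ct in sorted(types):
        genes = celltype_map.index[celltype_map == ct]
        genes = X.columns.intersection(genes)
        if len(genes) < 2:
            raise ValueError(f"cell type {ct!r} has fewer than 2 genes in the matrix")
        profile = X[genes].mean(axis=1).to_frame(name=ct)
        scaled = hemisphere_scale_genes(profile)[ct]
        for measure in beta_maps.columns:
            res = gene_profile_regression(scaled, beta_maps[measure], component_scores)
            rows.append({"cell_type": ct, "measure": measure, "n_genes": len(genes),
                         **{k: res[k] for k in ("beta", "se", "p", "unstable")}})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"])
    out["significant"] = out["q"] < alpha
    return out


def _dunn_vs_baseline(values: np.ndarray, groups: np.ndarray, baseline: str) -> pd.DataFrame:
    """Dunn post-hoc z tests of each group against the baseline group.

    Uses mean ranks of the full sample with the tie-corrected variance
    term; p-values are two-sided normal, Holm-adjusted across comparisons.
    """
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    var_unit = n * (n + 1) / 12.0 - tie_term
    base_mask = groups == baseline
    rb, nb = ranks[base_mask].mean(), base_mask.sum()
    rows = []
    for g in sorted(set(groups) - {baseline}):
        m = groups == g
        rg, ng = ranks[m].mean(), m.sum()
        se = np.sqrt(var_unit * (1.0 / ng + 1.0 / nb))
        z = (rg - rb) / se if se > 0 else 0.0
        rows.append({"group": g, "n": int(ng), "z": float(z),
                     "p_raw": float(2 * stats.norm.sf(abs(z)))})
    out = pd.DataFrame(rows).set_index("group")
    out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def celltype_loading_tests(loadings: pd.Series, celltype_map: pd.Series,
                           baseline: str = UNCLASSIFIED) -> dict:
    """Distribution of component loadings by cell type.

    Kruskal-Wallis H (tie-corrected) across all groups including the
    baseline, Dunn z for each type vs the baseline with Holm adjustment,
    and moment-based descriptives (Fisher-Pearson skewness g1 and excess
    kurtosis g2) per group.  Degenerate input (all values tied, or a
    single group) returns H = 0, p = 1 rather than failing.
    """
    idx = loadings.index.intersection(celltype_map.index)
    vals = loadings.loc[idx].to_numpy(dtype=float)
    groups = celltype_map.loc[idx].to_numpy()
    descriptives = []
    for g in sorted(set(groups)):
        v = vals[groups == g]
        descriptives.append({
            "cell_type": g, "n": int(len(v)), "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
            "skewness": float(stats.skew(v, bias=True)) if len(v) > 2 else np.nan,
            "kurtosis": float(stats.kurtosis(v, bias=True)) if len(v) > 3 else np.nan,
        })
    desc = pd.DataFrame(descriptives).set_index("cell_type")
    samples = [vals[groups == g] for g in sorted(set(groups))]
    eligible = [s for s in samples if len(s) >= 2]
    if len(eligible) < 2 or len(np.unique(vals)) == 1:
        return {"H": 0.0, "df": max(0, len(samples) - 1), "p": 1.0,
                "descriptives": desc, "dunn": None, "degenerate": True}
    H, p = stats.kruskal(*samples)
    dunn = (_dunn_vs_baseline(vals, groups, baseline)
            if baseline in groups else None)
    return {"H": float(H), "df": len(samples) - 1, "p": float(p),
            "descriptives": desc, "dunn": dunn, "degenerate": False}
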