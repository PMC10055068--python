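"""Principal components of the region-by-gene expression matrix.

The spatial structure of cortical gene expression is summarised by PCA on
the correlation matrix of genes across regions (each gene z-scored across
regions, so loadings are gene-component correlations bounded in [-1, 1]),
followed by varimax rotation with Kaiser normalization.  Component scores
place each region on the rotated components and may be re-standardized
within each hemisphere to remove hemisphere-level acquisition artifacts
(in the donor atlas the two hemispheres are sampled from different donor
counts, which shifts raw expression and hence raw scores by hemisphere).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import check_region_index, hemisphere_of


def varimax(loadings: np.ndarray, *, kaiser: bool = True, tol: float = 1e-10,
            max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Maximizes the variance of squared loadings within each column.  With
    ``kaiser=True`` rows are normalized to unit communality before
    rotation and rescaled afterwards (Kaiser normalization).  Returns the
    rotated loadings and the orthogonal rotation matrix ``R`` such that
    ``rotated = loadings @ R`` (applied to the normalized matrix).
    """
    L = np.array(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    h = np.sqrt((L ** 2).sum(axis=1))
    if kaiser:
        h_safe = np.where(h > 0, h, 1.0)
        A = L / h_safe[:, None]
    else:
        A = L
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = A @ R
        tmp = A.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(tmp)
        R = u @ vt
        d_old, d = d, s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
    Lrot = A @ R
    if kaiser:
        Lrot = Lrot * h[:, None]
    return Lrot, R


@dataclass
class ComponentSolution:
    """Loadings, scores and variance bookkeeping for k spatial components."""

    loadings: pd.DataFrame          # gene x k, correlation metric
    scores: pd.DataFrame            # region x k
    variance_explained_unrotated: np.ndarray
    variance_explained_rotated: np.ndarray
    rotation: np.ndarray            # k x k orthogonal (identity if unrotated)
    rotated: bool
    sign_flips: np.ndarray          # +1/-1 applied per component
    scaling: str = "global"         # "global" or "hemisphere"
    n_regions: int = 0
    n_genes: int = 0
    dropped_genes: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def component_names(self) -> list[str]:
        return list(self.loadings.columns)


def _standardize_genes(X: pd.DataFrame) -> np.ndarray:
    V = X.to_numpy(dtype=float)
    mu = V.mean(axis=0)
    sd = V.std(axis=0)  # population SD: correlation-matrix convention
    zero = sd == 0
    if zero.any():
        bad = list(np.asarray(X.columns)[zero][:10])
        raise ValueError(
            f"{int(zero.sum())} gene(s) are constant across regions "
            f"(zero variance), e.g. {bad}; drop them before fitting"
        )
    return (V - mu) / sd


def fit_components(X: pd.DataFrame, k: int = 2, rotate: bool = True,
                   kaiser: bool = True) -> ComponentSolution:
    """Correlation-matrix PCA of a region-by-gene table with optional varimax.

    Parameters
    ----------
    X : DataFrame
        Regions (hemisphere-tagged index) by genes. Genes with any missing
        region are dropped (and recorded); constant genes are an error.
    k : int
        Number of components to retain; must satisfy
        ``k <= min(n_regions - 1, n_genes)``.
    rotate : bool
        Apply varimax with Kaiser normalization to the k retained columns.
    """
    check_region_index(X.index)
    dropped = [g for g in X.columns[X.isna().any(axis=0)]]
    if dropped:
        X = X.drop(columns=dropped)
    n, p = X.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(n_regions - 1, n_genes) = {min(n - 1, p)}")
    Z = _standardize_genes(X)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s ** 2 / n
    var_unrot = eigvals[:k] / p
    # unrotated loadings: eigenvector * sqrt(eigenvalue) (gene-score correlation)
    L = Vt[:k].T * np.sqrt(eigvals[:k])

    if rotate and k >= 2:
        Lrot, R = varimax(L, kaiser=kaiser)
    else:
        Lrot, R = L.copy(), np.eye(k)

    # deterministic orientation: mean loading of each component >= 0
    flips = np.where(Lrot.mean(axis=0) < 0, -1.0, 1.0)
    Lrot = Lrot * flips
    var_rot = (Lrot ** 2).sum(axis=0) / p

    S = Z @ Lrot
    sd = S.std(axis=0)
    S = (S - S.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    names = [f"C{i + 1}" for i in range(k)]
    return ComponentSolution(
        loadings=pd.DataFrame(Lrot, index=X.columns, columns=names),
        scores=pd.DataFrame(S, index=X.index, columns=names),
        variance_explained_unrotated=var_unrot,
        variance_explained_rotated=var_rot,
        rotation=R,
        rotated=bool(rotate and k >= 2),
        sign_flips=flips,
        scaling="global",
        n_regions=n,
        n_genes=p,
        dropped_genes=dropped,
    )


def scale_scores_by_hemisphere(solution: ComponentSolution, ddof: int = 1) -> ComponentSolution:
    """Z-standardize each component's scores within each hemisphere.

    Removes additive hemisphere-level artifacts (e.g. unequal donor counts
    per hemisphere in the source atlas) from the regional score maps.
    """
    scores = solution.scores.copy()
    hemis = hemisphere_of(scores.index)
    for h in np.unique(hemis):
        mask = hemis == h
        if mask.sum() < 2:
            raise ValueError(f"hemisphere {h!r} has fewer than 2 regions; cannot scale")
        block = scores.loc[mask]
        scores.loc[mask] = (block - block.mean()) / block.std(ddof=ddof)
    return replace(solution, scores=scores, scaling="hemisphere")


def loading_threshold_sets(solution: ComponentSolution, cut: float = 0.3) -> dict:
    """Partition genes by |loading| threshold on each component.

    Returns per-component sets of genes with loading < -cut and > +cut,
    plus the four-way partition used for enrichment bookkeeping: genes
    above |cut| on both components, on only one, or on neither.
    """
    if not 0 <= cut < 1:
        raise ValueError("cut must lie in [0, 1)")
    L = solution.loadings
    out: dict = {"cut": cut, "per_component": {}, "n_genes": L.shape[0]}
    above_abs = {}
    for c in L.columns:
        col = L[c]
        below = set(col.index[col < -cut])
        above = set(col.index[col > cut])
        above_abs[c] = set(col.index[col.abs() > cut])
        out["per_component"][c] = {
            "below": below, "above": above,
            "n_below": len(below), "n_above": len(above),
        }
    comps = list(L.columns)
    if len(comps) >= 2:
        a, b = above_abs[comps[0]], above_abs[comps[1]]
        both = a & b
        only_a = a - b
        only_b = b - a
        neither = set(L.index) - a - b
        out["partition"] = {
            "both": both, f"only_{comps[0]}": only_a,
            f"only_{comps[1]}": only_b, "neither": neither,
        }
        out["partition_counts"] = {k: len(v) for k, v in out["partition"].items()}
    return out
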