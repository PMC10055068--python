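"""Stability of component solutions: Tucker congruence and cross-validation.

Tucker's congruence coefficient (phi) is the cosine between two loading
vectors and is the standard measure of factor similarity.  Stability of
the spatial components is probed two ways: (i) region-subset
cross-validation, refitting the PCA on complementary region partitions and
comparing matched components, and (ii) matched-gene congruence between
solutions fit on different datasets restricted to their shared genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .components import ComponentSolution, fit_components


def tucker_congruence(a, b) -> float:
    """Tucker congruence phi = sum(a*b) / sqrt(sum(a^2) * sum(b^2))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("inputs must be equal-length 1-d vectors of length >= 2")
    na, nb = np.sqrt((a ** 2).sum()), np.sqrt((b ** 2).sum())
    if na == 0 or nb == 0:
        raise ValueError("zero-norm loading vector")
    return float((a * b).sum() / (na * nb))


@dataclass
class CongruenceMatrix:
    """All-pairs congruence between two solutions plus a greedy matching."""

    phi: pd.DataFrame                       # rows = A components, cols = B
    matching: list                          # (a_comp, b_comp, abs_phi), one-to-one


def congruence_matrix(loadings_a: pd.DataFrame, loadings_b: pd.DataFrame) -> CongruenceMatrix:
    phi = pd.DataFrame(
        [[tucker_congruence(loadings_a[ca], loadings_b[cb]) for cb in loadings_b.columns]
         for ca in loadings_a.columns],
        index=loadings_a.columns, columns=loadings_b.columns, dtype=float,
    )
    matching = greedy_match(phi)
    return CongruenceMatrix(phi=phi, matching=matching)


def greedy_match(phi: pd.DataFrame) -> list:
    """One-to-one component matching by repeatedly taking the largest |phi|.

    Matching by congruence rather than by component index allows e.g. the
    second component of one dataset to pair with the third of another.
    """
    work = phi.abs().copy()
    out = []
    for _ in range(min(work.shape)):
        idx = np.unravel_index(np.nanargmax(work.to_numpy()), work.shape)
        a, b = work.index[idx[0]], work.columns[idx[1]]
        out.append((a, b, float(work.loc[a, b])))
        work.loc[a, :] = np.nan
        work.loc[:, b] = np.nan
    return out


@dataclass
class CvCongruenceResult:
    records: pd.DataFrame       # repeat, fold, component, abs_phi
    summary: pd.DataFrame       # per component: mean, sd of |phi|
    n_repeats: int
    n_folds: int
    seed: int
    fold_sizes: list


def _partition(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition of range(n) into n_folds near-equal parts.

    Remainder regions are spread one per fold, so at n=68, folds=5 the
    sizes are 14, 14, 14, 13, 13.
    """
    perm = rng.permutation(n)
    base = n // n_folds
    rem = n % n_folds
    sizes = [base + (1 if i < rem else 0) for i in range(n_folds)]
    folds, start = [], 0
    for sz in sizes:
        folds.append(np.sort(perm[start:start + sz]))
        start += sz
    return folds


def region_subset_cv(X: pd.DataFrame, k: int = 2, n_repeats: int = 50,
                     n_folds: int = 5, seed: int = 0, rotate: bool = True) -> CvCongruenceResult:
    """Region-subset cross-validation of component stability.

    Per repeat, the regions are partitioned into ``n_folds`` parts without
    replacement; for each fold the PCA (with rotation, by default) is fit
    separately on the complement and on the fold, and the matched-component
    absolute congruences are recorded — ``n_repeats * n_folds`` comparisons.
    """
    n = X.shape[0]
    if n < 2 * n_folds:
        raise ValueError("need at least 2 regions per fold")
    rng = np.random.default_rng(seed)
    rows = []
    fold_sizes = None
    for rep in range(n_repeats):
        folds = _partition(n, n_folds, rng)
        if fold_sizes is None:
            fold_sizes = sorted(len(f) for f in folds)
        for ifold, fold in enumerate(folds):
            if len(fold) <= k:
                raise ValueError(f"fold of size {len(fold)} too small for k={k} components")
            test = X.iloc[fold]
            train = X.drop(index=test.index)
            sol_tr = fit_components(train, k=k, rotate=rotate)
            sol_te = fit_components(test, k=k, rotate=rotate)
            cm = congruence_matrix(sol_tr.loadings, sol_te.loadings)
            for a_comp, _, aphi in cm.matching:
                rows.append((rep, ifold, a_comp, aphi))
    records = pd.DataFrame(rows, columns=["repeat", "fold", "component", "abs_phi"])
    summary = records.groupby("component")["abs_phi"].agg(["mean", "std", "count"])
    return CvCongruenceResult(records=records, summary=summary,
                              n_repeats=n_repeats, n_folds=n_folds,
                              seed=seed, fold_sizes=fold_sizes)


def matched_gene_congruence(solution_a: ComponentSolution, solution_b: ComponentSolution,
                            id_map_a=None, id_map_b=None) -> CongruenceMatrix:
    """Congruence between two solutions on their shared genes.

    Optional ``id_map_*`` dictionaries translate each solution's gene
    identifiers to a common namespace before intersecting.
    """
    la, lb = solution_a.loadings, solution_b.loadings
    if id_map_a is not None:
        la = la.rename(index=id_map_a)
    if id_map_b is not None:
        lb = lb.rename(index=id_map_b)
    shared = la.index.intersection(lb.index)
    if len(shared) == 0:
        raise ValueError("no shared gene identifiers between solutions")
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes; need >= 10 for congruence")
    shared = shared.sort_values()
    return congruence_matrix(la.loc[shared], lb.loc[shared])
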