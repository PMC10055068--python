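"""Associations between regional maps (scores, pooled betas, mean maps).

A "regional map" is a Series of one value per hemisphere-tagged region.
The headline tests relate the absolute component scores of gene
expression to the pooled g-morphometry beta maps ("correlations of
correlations"), with a quadratic-regression variant on the signed scores.
p-values are plain parametric two-sided tests treating regions as
exchangeable units; no spatial-autocorrelation correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import paired_labels

log = logging.getLogger(__name__)


@dataclass
class MapAssociation:
    r: float
    p: float
    n: int
    model: str = "plain"           # plain | linear-absolute | quadratic
    coefficients: dict | None = None


def _align(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, np.ndarray, int]:
    shared = a.index.intersection(b.index)
    x = a.loc[shared].to_numpy(dtype=float)
    y = b.loc[shared].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    dropped = len(shared) - ok.sum()
    if dropped:
        log.info("map association: dropped %d regions with missing values", dropped)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 shared non-missing regions")
    return x[ok], y[ok], int(ok.sum())


def map_correlation(a: pd.Series, b: pd.Series, model: str = "plain") -> MapAssociation:
    """Pearson correlation between two label-aligned regional maps."""
    x, y, n = _align(a, b)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a regional map")
    r, p = stats.pearsonr(x, y)
    return MapAssociation(r=float(r), p=float(p), n=n, model=model)


def interhemispheric_correlation(values: pd.Series) -> MapAssociation:
    """Correlation between paired left/right region values (n = 34 pairs)."""
    pairs = paired_labels(values.index)
    left = values.loc[[p[0] for p in pairs]].to_numpy(dtype=float)
    right = values.loc[[p[1] for p in pairs]].to_numpy(dtype=float)
    r, p = stats.pearsonr(left, right)
    return MapAssociation(r=float(r), p=float(p), n=len(pairs), model="interhemispheric")


def absolute_component_association(scores: pd.Series, beta_map: pd.Series) -> MapAssociation:
    """Pearson r between |component score| and a pooled beta map.

    A negative r means that regions far from the balance point of the
    component (large |score| in either direction) have weaker
    g-morphometry associations.
    """
    return map_correlation(scores.abs(), beta_map, model="linear-absolute")


def quadratic_component_association(scores: pd.Series, beta_map: pd.Series) -> MapAssociation:
    """OLS of the beta map on the signed score and its square.

    The quadratic coefficient is the signed-score analogue of the
    absolute-score correlation (an inverted-U if negative).
    """
    x, y, n = _align(scores, beta_map)
    X = np.column_stack([np.ones(n), x, x ** 2])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - 3
    sigma2 = resid @ resid / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tq = coef[2] / se[2] if se[2] > 0 else np.inf
    pq = float(2 * stats.t.sf(abs(tq), dof)) if dof > 0 else np.nan
    yhat = X @ coef
    r = float(np.corrcoef(yhat, y)[0, 1]) if y.std() > 0 and yhat.std() > 0 else np.nan
    return MapAssociation(
        r=r, p=pq, n=n, model="quadratic",
        coefficients={"intercept": float(coef[0]), "linear": float(coef[1]),
                      "quadratic": float(coef[2]),
                      "se": {"intercept": float(se[0]), "linear": float(se[1]),
                             "quadratic": float(se[2])}},
    )


def mean_map_controls(expression: pd.DataFrame, beta_maps: pd.DataFrame,
                      mean_morphometry: pd.DataFrame | None = None,
                      scores: pd.DataFrame | None = None) -> dict:
    """Control analyses against simple regional means.

    Correlates (i) regional mean expression (across genes) with each beta
    map, and optionally (ii) regional mean morphometry with component
    scores and with beta maps.  Near-zero mean-expression correlations
    demonstrate that component-score associations are not reducible to a
    brain-wide average expression pattern.
    """
    mean_expr = expression.mean(axis=1)
    out: dict = {"mean_expression_vs_beta": {}}
    for m in beta_maps.columns:
        out["mean_expression_vs_beta"][m] = map_correlation(mean_expr, beta_maps[m])
    if mean_morphometry is not None:
        out["mean_morphometry_vs_beta"] = {}
        out["mean_morphometry_vs_scores"] = {}
        for m in mean_morphometry.columns:
            if m in beta_maps.columns:
                out["mean_morphometry_vs_beta"][m] = map_correlation(
                    mean_morphometry[m], beta_maps[m])
            if scores is not None:
                out["mean_morphometry_vs_scores"][m] = {
                    c: map_correlation(mean_morphometry[m], scores[c])
                    for c in scores.columns
                }
    return out
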