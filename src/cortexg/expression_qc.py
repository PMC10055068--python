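"""Donor-consistency quality control and the median regional expression matrix.

Donor-level regional expression profiles are summarised to a single
region-by-gene matrix by taking, per (region, gene), the median across
donors.  Genes whose regional profiles are not reproducible across donors
are removed beforehand: for each gene, each donor's left-hemisphere
regional profile is correlated (Spearman) with the cross-donor median
profile; genes whose mean correlation exceeds a fixed threshold
(default 0.446, calibrated to one-sided p < .05) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import hemisphere_of

#: Donor-consistency retention threshold (mean donor-to-median Spearman rho).
CONSISTENCY_THRESHOLD = 0.446


@dataclass
class DonorProfiles:
    """Donor-level expression in long format (donor, region, gene, value)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"donor", "region", "gene", "value"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"donor profile table missing columns: {sorted(missing)}")
        if self.table.empty:
            raise ValueError("empty donor profile table")
        dup = self.table.duplicated(subset=["donor", "region", "gene"])
        if dup.any():
            raise ValueError(
                f"{int(dup.sum())} duplicate (donor, region, gene) entries"
            )

    @property
    def donors(self) -> np.ndarray:
        return self.table["donor"].unique()

    def to_cube(self) -> pd.DataFrame:
        """Wide layout: (donor, region) x gene."""
        return self.table.pivot_table(index=["donor", "region"], columns="gene",
                                      values="value", aggfunc="mean")


@dataclass
class ConsistencyReport:
    per_gene: pd.DataFrame     # gene, mean_rho, retained
    threshold: float
    hemisphere: str

    @property
    def retained_genes(self) -> list:
        return list(self.per_gene.index[self.per_gene["retained"]])

    @property
    def dropped_genes(self) -> list:
        return list(self.per_gene.index[~self.per_gene["retained"]])


def median_regional_expression(profiles: DonorProfiles) -> pd.DataFrame:
    """Across-donor median expression per (region, gene).

    If multiple samples per (donor, region, gene) are supplied they are
    first averaged within donor; the cross-donor summary is the median.
    Regions missing for every donor simply do not appear; (region, gene)
    cells missing for some donors are the median of the available donors.
    """
    cube = profiles.to_cube()
    out = cube.groupby(level="region").median()
    out.index.name = "region"
    out.columns.name = "gene"
    return out


def donor_consistency_filter(profiles: DonorProfiles,
                             threshold: float = CONSISTENCY_THRESHOLD,
                             hemisphere: str = "L") -> ConsistencyReport:
    """Retain genes with reproducible regional profiles across donors.

    For each gene: Spearman rho between each donor's regional profile
    (restricted to ``hemisphere``) and the cross-donor median profile
    (including that donor), averaged over donors; retained iff the mean
    rho strictly exceeds ``threshold``.  A donor profile that is constant
    across regions has no defined rank correlation and contributes 0 to
    the average — a conservative choice that pushes degenerate genes
    toward exclusion.
    """
    cube = profiles.to_cube()
    regions = cube.index.get_level_values("region").unique()
    keep_regions = regions[hemisphere_of(regions) == hemisphere]
    if len(keep_regions) < 3:
        raise ValueError(
            f"fewer than 3 regions in hemisphere {hemisphere!r}; "
            "rank correlation of profiles is not meaningful"
        )
    sub = cube.loc[cube.index.get_level_values("region").isin(keep_regions)]
    donors = sub.index.get_level_values("donor").unique()
    if len(donors) < 2:
        raise ValueError("need at least 2 donors for consistency testing")

    median_profile = sub.groupby(level="region").median()  # region x gene
    mean_rho = np.zeros(sub.shape[1])
    for donor in donors:
        prof = sub.xs(donor, level="donor").reindex(median_profile.index)
        rho = _columnwise_spearman(prof.to_numpy(), median_profile.to_numpy())
        mean_rho += np.where(np.isnan(rho), 0.0, rho)
    mean_rho /= len(donors)

    per_gene = pd.DataFrame({"mean_rho": mean_rho, "retained": mean_rho > threshold},
                            index=sub.columns)
    per_gene.index.name = "gene"
    return ConsistencyReport(per_gene=per_gene, threshold=threshold, hemisphere=hemisphere)


def _columnwise_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman rho between matching columns of a and b (NaN if undefined).

    Average ranks for ties; pairwise-complete rows per column.
    """
    out = np.full(a.shape[1], np.nan)
    for j in range(a.shape[1]):
        x, y = a[:, j], b[:, j]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            continue
        xr = stats.rankdata(x[ok])
        yr = stats.rankdata(y[ok])
        sx, sy = xr.std(), yr.std()
        if sx == 0 or sy == 0:
            continue  # constant profile: rho undefined
        out[j] = np.corrcoef(xr, yr)[0, 1]
    return out


def apply_filter(matrix: pd.DataFrame, report: ConsistencyReport) -> pd.DataFrame:
    """Restrict an expression matrix to the retained genes."""
    return matrix.loc[:, matrix.columns.intersection(report.retained_genes)]
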