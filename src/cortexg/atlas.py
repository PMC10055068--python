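"""Cortical parcellation labels and hemisphere helpers.

Regions follow the Desikan-Killiany (DK) atlas convention: 34 paired
cortical regions per hemisphere, labelled ``lh_<name>`` / ``rh_<name>``.
All tabular structures in this package index regions by these labels and
infer hemisphere membership from the prefix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: The 34 Desikan-Killiany cortical region names (one hemisphere).
DK_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

LEFT = "L"
RIGHT = "R"


def region_labels(n_per_hemisphere: int = 34) -> list[str]:
    """Hemisphere-tagged region labels, left hemisphere first.

    For up to 34 regions per hemisphere the DK names are used; larger
    parcellations fall back to numbered labels.
    """
    if n_per_hemisphere <= len(DK_REGIONS):
        names = DK_REGIONS[:n_per_hemisphere]
    else:
        names = tuple(f"region{i:03d}" for i in range(n_per_hemisphere))
    return [f"lh_{n}" for n in names] + [f"rh_{n}" for n in names]


def hemisphere_of(labels) -> np.ndarray:
    """Map region labels to hemisphere codes ('L'/'R').

    Raises ``ValueError`` for labels without a recognised prefix.
    """
    out = []
    for lab in labels:
        if lab.startswith("lh_"):
            out.append(LEFT)
        elif lab.startswith("rh_"):
            out.append(RIGHT)
        else:
            raise ValueError(f"region label {lab!r} lacks an lh_/rh_ hemisphere prefix")
    return np.asarray(out)


def paired_labels(labels) -> list[tuple[str, str]]:
    """(left, right) label pairs sharing the same base region name.

    Unpaired labels are an error: interhemispheric operations require
    every region to have its contralateral homologue.
    """
    base_left = {lab[3:]: lab for lab in labels if lab.startswith("lh_")}
    base_right = {lab[3:]: lab for lab in labels if lab.startswith("rh_")}
    if set(base_left) != set(base_right):
        odd = sorted(set(base_left) ^ set(base_right))
        raise ValueError(f"unpaired region labels: {odd}")
    return [(base_left[b], base_right[b]) for b in sorted(base_left)]


def check_region_index(index: pd.Index) -> None:
    if index.duplicated().any():
        dups = index[index.duplicated()].tolist()
        raise ValueError(f"duplicate region labels: {dups}")
    hemisphere_of(index)  # validates prefixes
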