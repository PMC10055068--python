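"""Plain-text readers and writers for the pipeline's tabular artifacts.

All tables are headered TSV/CSV; nested summaries are JSON.  Expression
matrices are regions x genes with the region label in the first column;
donor profiles are long format (donor, region, gene, value); regional
maps are (region, value) pairs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_expression_matrix(X: pd.DataFrame, path) -> None:
    X.to_csv(path, sep="\t", index_label="region")


def read_expression_matrix(path) -> pd.DataFrame:
    X = pd.read_csv(path, sep="\t", index_col="region")
    X.columns.name = "gene"
    return X


def write_donor_profiles(profiles, path) -> None:
    profiles.table.to_csv(path, sep="\t", index=False)


def read_donor_profiles(path):
    from .expression_qc import DonorProfiles

    return DonorProfiles(pd.read_csv(path, sep="\t"))


def write_regional_map(values: pd.Series, path, value_name: str = "value") -> None:
    from .atlas import hemisphere_of

    df = pd.DataFrame({"region": values.index,
                       "hemisphere": hemisphere_of(values.index),
                       value_name: values.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


def read_regional_map(path, value_name: str | None = None) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    col = value_name or df.columns[-1]
    return pd.Series(df[col].to_numpy(), index=pd.Index(df["region"], name="region"),
                     name=col)


def write_loadings(loadings: pd.DataFrame, path) -> None:
    loadings.to_csv(path, sep="\t", index_label="gene")


def read_loadings(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_scores(scores: pd.DataFrame, path) -> None:
    from .atlas import hemisphere_of

    out = scores.copy()
    out.insert(0, "hemisphere", hemisphere_of(scores.index))
    out.to_csv(path, sep="\t", index_label="region")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n")


def _jsonify(obj):
    import dataclasses

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonify(v) for v in sorted(obj)] if isinstance(obj, set) else [
            _jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="index"))
    return obj


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
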