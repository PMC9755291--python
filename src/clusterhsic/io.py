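"""Reading feature tables and cluster maps from delimited text.

Feature tables: one header row, first column the sample identifier, the
remaining columns numeric features.  Comma- or tab-delimited, auto-detected
by extension (.csv -> comma, anything else -> tab).  Row order defines the
sample order of the X table; Y and the cluster map are aligned to it by ID.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment

__all__ = ["read_feature_table", "read_cluster_map", "align_tables"]


def _sep_for(path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_feature_table(path) -> pd.DataFrame:
    """Read a samples-by-features table; index = sample IDs."""
    # round_trip parsing keeps write->read bitwise exact for float64 values
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no feature columns found")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric feature values ({exc})") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError(f"{path}: missing or non-finite values are not supported")
    df.index = df.index.astype(str)
    return df


def read_cluster_map(path) -> pd.Series:
    """Read a two-column sample-ID -> cluster-label map; index = sample IDs."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] != 1:
        raise ValueError(
            f"{path}: cluster map must have exactly two columns "
            f"(sample ID, cluster label), found {df.shape[1] + 1}"
        )
    s = df.iloc[:, 0]
    s.index = s.index.astype(str)
    if s.index.duplicated().any():
        dup = s.index[s.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    return s


def align_tables(
    x: pd.DataFrame, y: pd.DataFrame, cluster_map: pd.Series | None = None
):
    """Align Y (and the cluster map) to X's sample order by ID.

    Returns ``(X_values, Y_values, clusters_or_None)``; raises on the first
    sample ID missing from either side.
    """
    for name, other in (("Y", y.index), ("cluster map", None if cluster_map is None else cluster_map.index)):
        if other is None:
            continue
        missing = x.index.difference(other)
        if len(missing):
            raise ValueError(f"sample ID {missing[0]!r} is missing from the {name}")
        extra = other.difference(x.index)
        if len(extra):
            raise ValueError(f"sample ID {extra[0]!r} in the {name} is absent from X")
    y = y.loc[x.index]
    clusters = None
    if cluster_map is not None:
        clusters = ClusterAssignment(cluster_map.loc[x.index].to_numpy())
    return x.to_numpy(float), y.to_numpy(float), clusters
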