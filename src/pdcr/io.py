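"""CSV readers and writers for feature tables and label files."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import FeatureTable, LabelData, encode_labels

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_labels",
    "write_labels",
    "align_labels",
]


def read_feature_table(path, orientation: str = "samples-rows") -> FeatureTable:
    """Read a feature table CSV.

    Layout ``samples-rows``: header row = feature names, first column =
    sample id. ``features-rows`` reads the transposed layout. Duplicate
    identifiers and non-numeric cells are rejected with coordinates.
    """
    if orientation not in ("samples-rows", "features-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    # pandas mangles duplicate header names (f, f.1); check the raw header
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    cols = header[1:]
    if len(set(cols)) != len(cols):
        dup = next(c for i, c in enumerate(cols) if c in cols[:i])
        kind = "feature" if orientation == "samples-rows" else "sample"
        raise ValueError(f"duplicate {kind} id {dup!r} in {path}")
    df = pd.read_csv(path, index_col=0)
    if orientation == "features-rows":
        df = df.T
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate feature id {dup!r} in {path}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(values) & ~df.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-numeric cell at sample {df.index[i]!r}, feature {df.columns[j]!r} in {path}"
        )
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing value at sample {df.index[i]!r}, feature {df.columns[j]!r} in {path}"
        )
    return FeatureTable(
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(f) for f in df.columns],
        values=values,
    )


def write_feature_table(table: FeatureTable, path) -> None:
    pd.DataFrame(
        table.values, index=table.sample_ids, columns=table.feature_ids
    ).to_csv(path, index_label="sample_id")


def read_labels(path) -> pd.Series:
    """Two-column CSV (sample_id, label) -> Series indexed by sample id."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs columns sample_id,label")
    ser = df.set_index(df.columns[0])[df.columns[1]]
    if ser.index.has_duplicates:
        dup = ser.index[ser.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    return ser


def write_labels(sample_ids: list[str], labels: list[str], path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "label": labels}).to_csv(path, index=False)


def align_labels(table: FeatureTable, labels: pd.Series) -> LabelData:
    """Join labels onto the table's sample order; the join must be total."""
    missing = [s for s in table.sample_ids if s not in labels.index]
    if missing:
        raise ValueError(f"samples without a label: {missing[:5]}")
    return encode_labels([labels[s] for s in table.sample_ids])
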