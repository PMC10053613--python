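"""Feature-table container and CSV/JSON readers and writers.

The on-disk interchange format is a plain CSV with one row per sample,
numeric feature columns, and a final label column taking exactly two
distinct values. Labels are normalised internally to {1, 2} (class 1 is
the "positive" class throughout the package), with the original-to-internal
mapping recorded so reports remain traceable to the input file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "read_feature_csv", "write_feature_csv"]


@dataclasses.dataclass
class FeatureTable:
    """A samples x features numeric matrix with binary labels in {1, 2}."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    label_mapping: dict[Any, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y must have one label per row of X")
        bad = set(np.unique(self.y)) - {1, 2}
        if bad:
            raise ValueError(f"internal labels must be in {{1, 2}}, got extra {sorted(bad)}")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match the number of columns")
        if not self.label_mapping:
            self.label_mapping = {1: 1, 2: 2}

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["label"] = self.y
        return df

    def restrict(self, mask: np.ndarray) -> "FeatureTable":
        """Return the table restricted to the columns where ``mask`` is set."""
        mask = np.asarray(mask).astype(bool)
        if mask.shape != (self.n_features,):
            raise ValueError("mask length must match the number of features")
        names = [n for n, m in zip(self.feature_names, mask) if m]
        return FeatureTable(self.X[:, mask], self.y, names, dict(self.label_mapping))


def read_feature_csv(path: str | Path, label_col: str = "label") -> FeatureTable:
    """Read a feature table from CSV, mapping the two label values to {1, 2}.

    The two distinct label values are mapped in sorted order (smaller -> 1,
    larger -> 2; strings sort lexicographically), and the mapping is recorded
    on the returned table.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if label_col not in df.columns:
        raise ValueError(f"{path}: missing label column {label_col!r}")

    feature_cols = [c for c in df.columns if c != label_col]
    if not feature_cols:
        raise ValueError(f"{path}: no feature columns")
    for col in feature_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: non-numeric value {df[col][row]!r} in column {col!r}, row {row}"
            )
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ValueError(f"{path}: missing value in column {col!r}, row {row}")
        df[col] = numeric

    levels = sorted(pd.unique(df[label_col]))
    if len(levels) != 2:
        raise ValueError(
            f"{path}: label column must take exactly 2 distinct values, got {len(levels)}"
        )
    mapping = {levels[0]: 1, levels[1]: 2}
    y = df[label_col].map(mapping).to_numpy()
    return FeatureTable(df[feature_cols].to_numpy(dtype=float), y, feature_cols, mapping)


def write_feature_csv(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV (labels written in internal {1, 2} form)."""
    table.to_dataframe().to_csv(path, index=False)


def write_sidecar(path: str | Path, payload: dict) -> None:
    """Write a JSON sidecar (ground truth / provenance) next to a CSV."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
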