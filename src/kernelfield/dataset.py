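"""Labelled feature datasets and their delimited-text round trips."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class LabeledDataset:
    """A feature matrix with integer class labels and sample ids."""

    X: np.ndarray
    labels: np.ndarray
    ids: tuple
    feature_names: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.ids = tuple(str(i) for i in self.ids)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got ndim={self.X.ndim}")
        n = self.X.shape[0]
        if len(self.labels) != n or len(self.ids) != n:
            raise ValueError(
                f"inconsistent dataset: {n} rows, {len(self.labels)} labels, {len(self.ids)} ids"
            )
        if len(set(self.ids)) != n:
            raise ValueError("duplicate sample ids")
        if self.feature_names is not None:
            self.feature_names = tuple(self.feature_names)
            if len(self.feature_names) != self.X.shape[1]:
                raise ValueError("feature_names length does not match column count")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def class_sizes(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def subset(self, index) -> "LabeledDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return LabeledDataset(
            X=self.X[index],
            labels=self.labels[index],
            ids=tuple(self.ids[i] for i in index),
            feature_names=self.feature_names,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = self.feature_names or tuple(f"f{j}" for j in range(self.X.shape[1]))
        df = pd.DataFrame(self.X, columns=list(cols), index=list(self.ids))
        df.index.name = "id"
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def read_feature_table(path) -> LabeledDataset:
    """Read a feature table (CSV with id index and a final ``label`` column)."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if "label" not in df.columns:
        raise ValueError(f"{path}: feature table must have a 'label' column")
    labels = df.pop("label").to_numpy()
    return LabeledDataset(
        X=df.to_numpy(dtype=float),
        labels=labels,
        ids=tuple(str(i) for i in df.index),
        feature_names=tuple(df.columns),
    )


def read_label_table(path) -> dict:
    """Read a two-column TSV ``id<TAB>label`` (with header) into a dict."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if list(df.columns[:2]) != ["id", "label"]:
        raise ValueError(f"{path}: expected header 'id\\tlabel', got {list(df.columns)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"{path}: duplicate id {dup!r} in label table")
    return {str(r.id): int(r.label) for r in df.itertuples()}


def write_label_table(path, ids: Sequence, labels: Sequence) -> None:
    df = pd.DataFrame({"id": [str(i) for i in ids], "label": [int(l) for l in labels]})
    df.to_csv(path, sep="\t", index=False)
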