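"""The instances-by-features container shared by all featurizers and models."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class DescriptorMatrix:
    """Instances x named features with optional binary labels.

    ``data`` is a DataFrame indexed by instance id with one column per
    feature; ``labels`` (if present) is an int array aligned with the rows
    (1 = positive class).  Feature names are unique and values finite.
    """

    data: pd.DataFrame
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes[:5]}")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("descriptor matrix contains non-finite entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.size != len(self.data):
                raise ValueError("labels length does not match instance count")

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_instances(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def select(self, names: Sequence[str]) -> "DescriptorMatrix":
        """Column subset (name-based, order as given)."""
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {missing[:5]}")
        return DescriptorMatrix(self.data.loc[:, list(names)].copy(), self.labels)

    def with_labels(self, labels: np.ndarray) -> "DescriptorMatrix":
        return DescriptorMatrix(self.data.copy(), np.asarray(labels, dtype=int))

    def hstack(self, other: "DescriptorMatrix") -> "DescriptorMatrix":
        """Join two matrices over identical instances."""
        if list(self.data.index) != list(other.data.index):
            raise ValueError("instance ids differ; cannot join matrices")
        joined = pd.concat([self.data, other.data], axis=1)
        return DescriptorMatrix(joined, self.labels)

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as TSV: first column ``id``, optional ``label``, then features."""
        out = self.data.copy()
        if self.labels is not None:
            out.insert(0, "label", self.labels)
        out.index.name = "id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DescriptorMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        df.index = df.index.astype(str)
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy(dtype=int)
        return cls(df.astype(float), labels)
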