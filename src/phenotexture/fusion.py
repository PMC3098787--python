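"""Feature tables, [-1, 1] normalization, and block concatenation.

Heterogeneous descriptor blocks (co-occurrence statistics, curvelet subband
statistics, ...) live on very different numeric ranges.  Before they are
combined into a single vector, every feature is affinely mapped to
``[-1, 1]`` using the minimum and maximum observed *on the training rows
only*; test-set values outside the training range are deliberately not
clipped, so their ordering information survives.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "NormalizerParams",
    "fit_normalizer",
    "apply_normalizer",
    "combine_features",
]


@dataclass
class FeatureTable:
    """Named feature matrix (rows = images) with class labels.

    ``X`` is a float DataFrame indexed by image id; ``y`` is an aligned
    Series of class labels.
    """

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("feature matrix and labels must share the same index")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def classes(self) -> list:
        return sorted(self.y.unique())

    def subset(self, index) -> "FeatureTable":
        return FeatureTable(X=self.X.loc[index], y=self.y.loc[index])

    def to_csv(self, path: str | Path) -> None:
        """Serialize as CSV: image id, named features, then a label column."""
        df = self.X.copy()
        df.insert(0, "image_id", self.X.index)
        df["label"] = self.y.values
        df.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        if df.shape[1] < 3 or df.columns[0] != "image_id" or df.columns[-1] != "label":
            raise ValueError(
                f"{path}: expected columns image_id, <features...>, label"
            )
        df = df.set_index("image_id")
        y = df.pop("label")
        return cls(X=df.astype(float), y=y)


@dataclass(frozen=True)
class NormalizerParams:
    """Per-feature min/max fitted on training rows; maps those rows to [-1, 1]."""

    mins: pd.Series
    maxs: pd.Series

    @property
    def feature_names(self) -> list[str]:
        return list(self.mins.index)

    @property
    def constant_columns(self) -> list[str]:
        eq = self.maxs == self.mins
        return list(self.mins.index[eq])


def fit_normalizer(train_table: FeatureTable) -> NormalizerParams:
    if train_table.n_samples < 2:
        raise ValueError("need at least 2 rows to fit a normalizer")
    return NormalizerParams(mins=train_table.X.min(axis=0), maxs=train_table.X.max(axis=0))


def apply_normalizer(table: FeatureTable, params: NormalizerParams) -> FeatureTable:
    """Affine per-column map onto [-1, 1] (constant training columns -> 0).

    Values outside the fitted range map outside [-1, 1]; no clipping.
    """
    if list(table.X.columns) != params.feature_names:
        raise ValueError("feature names do not match the fitted normalizer")
    span = (params.maxs - params.mins).to_numpy()
    mins = params.mins.to_numpy()
    x = table.X.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        xn = 2.0 * (x - mins) / span - 1.0
    xn[:, span == 0] = 0.0
    return FeatureTable(
        X=pd.DataFrame(xn, index=table.X.index, columns=table.X.columns),
        y=table.y,
    )


def combine_features(blocks: Sequence[FeatureTable]) -> FeatureTable:
    """Column-wise concatenation of feature blocks sharing rows and labels.

    Column order follows the given block order (order-sensitive).
    """
    if not blocks:
        raise ValueError("need at least one feature block")
    first = blocks[0]
    for b in blocks[1:]:
        if not b.X.index.equals(first.X.index):
            raise ValueError("blocks must have identical row ordering")
        if not b.y.equals(first.y):
            raise ValueError("blocks must carry identical labels")
    names = [n for b in blocks for n in b.X.columns]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names across blocks")
    return FeatureTable(X=pd.concat([b.X for b in blocks], axis=1), y=first.y)
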