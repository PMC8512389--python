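"""Core containers shared across the package.

A candidate feature subset is a *solution mask*: a binary vector of length
N (one entry per candidate feature), 1 meaning the feature is selected.
The evaluation substrate is a :class:`FeatureMatrix`: one row per
sliding window, one named numeric column per feature, plus a class label
per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix", "mask_to_bitstring", "bitstring_to_mask", "mask_indices", "hamming"]


def mask_to_bitstring(mask: np.ndarray) -> str:
    """Render a binary mask as e.g. ``'10110'``."""
    return "".join("1" if b else "0" for b in np.asarray(mask).astype(int))


def bitstring_to_mask(bits: str) -> np.ndarray:
    """Parse ``'10110'`` into a uint8 mask array."""
    return np.array([int(c) for c in bits], dtype=np.uint8)


def mask_indices(mask: np.ndarray) -> list[int]:
    """Sorted 0-based indices of the selected features."""
    return [int(i) for i in np.flatnonzero(np.asarray(mask) != 0)]


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance between two equal-length binary masks."""
    a = np.asarray(a).astype(np.uint8)
    b = np.asarray(b).astype(np.uint8)
    if a.shape != b.shape:
        raise ValueError(f"mask length mismatch: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


@dataclass
class FeatureMatrix:
    """Windows-by-features table with one class label per window.

    Parameters
    ----------
    features
        Numeric DataFrame; columns are feature names, rows are windows.
    labels
        Per-row class labels (any hashable values), length = n rows.
    """

    features: pd.DataFrame
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.features):
            raise ValueError(
                f"label count {len(self.labels)} != row count {len(self.features)}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def values(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Feature values as a float array, optionally restricted to a mask."""
        x = self.features.to_numpy(dtype=float)
        if mask is None:
            return x
        mask = np.asarray(mask)
        if mask.shape[0] != self.n_features:
            raise ValueError(
                f"mask length {mask.shape[0]} != feature count {self.n_features}"
            )
        return x[:, mask.astype(bool)]

    def select(self, mask: np.ndarray) -> "FeatureMatrix":
        """New FeatureMatrix restricted to the masked-in columns."""
        mask = np.asarray(mask).astype(bool)
        return FeatureMatrix(self.features.loc[:, mask], self.labels.copy())

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        """Single DataFrame with the label as the last column."""
        out = self.features.copy()
        out[label_column] = self.labels
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label_column: str = "label") -> "FeatureMatrix":
        if label_column not in frame.columns:
            raise ValueError(f"label column {label_column!r} not present")
        labels = frame[label_column].to_numpy()
        feats = frame.drop(columns=[label_column])
        return cls(feats, labels)
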