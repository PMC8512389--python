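"""Readers and writers for feature tables and recordings.

Feature tables round-trip through CSV (header row, label last) and ARFF
(numeric attributes plus a nominal class attribute last) — the two
layouts the public HAR distributions use.  Missing feature cells are
imputed with the column mean on read.  Recordings use a CSV layout of
t, ax, ay, az, gx, gy, gz[, label].
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

from .core import FeatureMatrix
from .signal_prep import Recording

__all__ = ["read_table", "write_table", "read_recording", "write_recording"]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"csv", "arff"}:
        return suffix
    raise ValueError(f"cannot infer table format from {path.name!r}")


def _finalize(frame: pd.DataFrame, label_column: str | None) -> FeatureMatrix:
    label_column = label_column or frame.columns[-1]
    if label_column not in frame.columns:
        raise ValueError(f"label column {label_column!r} not present")
    labels = frame[label_column].to_numpy()
    feats = frame.drop(columns=[label_column])
    for col in feats.columns:
        coerced = pd.to_numeric(feats[col], errors="coerce")
        # cells that fail coercion but were non-null are genuinely non-numeric
        bad = coerced.isna() & feats[col].notna() & (feats[col].astype(str) != "?")
        if bad.any():
            raise ValueError(f"feature column {col!r} holds non-numeric values")
        feats[col] = coerced
    # column-mean imputation of missing cells
    feats = feats.apply(lambda c: c.fillna(c.mean()))
    return FeatureMatrix(feats, labels)


def read_table(path: str | Path, fmt: str | None = None,
               label_column: str | None = None) -> FeatureMatrix:
    """Read a labeled feature table from CSV or ARFF."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        frame = pd.read_csv(path)
    elif fmt == "arff":
        data, meta = scipy_arff.loadarff(str(path))
        frame = pd.DataFrame(data)
        for col in frame.columns:
            if frame[col].dtype == object:
                frame[col] = frame[col].str.decode("utf-8")
    else:
        raise ValueError(f"unknown table format {fmt!r}")
    return _finalize(frame, label_column)


def write_table(matrix: FeatureMatrix, path: str | Path,
                fmt: str | None = None, relation: str = "features") -> None:
    """Write a feature table as CSV or ARFF (nominal class attribute last)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        matrix.to_frame().to_csv(path, index=False)
        return
    if fmt != "arff":
        raise ValueError(f"unknown table format {fmt!r}")
    classes = sorted(str(c) for c in np.unique(matrix.labels))
    lines = [f"@relation {relation}", ""]
    for name in matrix.feature_names:
        lines.append(f"@attribute {name} numeric")
    lines.append("@attribute class {" + ",".join(classes) + "}")
    lines.append("")
    lines.append("@data")
    x = matrix.values()
    for row, label in zip(x, matrix.labels):
        lines.append(",".join(repr(float(v)) for v in row) + f",{label}")
    path.write_text("\n".join(lines) + "\n")


def write_recording(recording: Recording, path: str | Path) -> None:
    """CSV layout: t, one column per channel, optional label column."""
    n = recording.n_samples
    data = {"t": np.arange(n) / recording.fs}
    data.update({k: v for k, v in recording.channels.items()})
    if recording.labels is not None:
        data["label"] = recording.labels
    pd.DataFrame(data).to_csv(path, index=False)


def read_recording(path: str | Path, fs: float | None = None) -> Recording:
    """Read a recording CSV; fs inferred from the t column if not given."""
    frame = pd.read_csv(path)
    if fs is None:
        if "t" not in frame.columns or len(frame) < 2:
            raise ValueError("cannot infer fs: need a t column with >= 2 rows")
        dt = float(np.median(np.diff(frame["t"].to_numpy())))
        fs = 1.0 / dt
    labels = frame["label"].to_numpy() if "label" in frame.columns else None
    channels = {c: frame[c].to_numpy(dtype=float)
                for c in frame.columns if c not in {"t", "label"}}
    return Recording(channels=channels, fs=fs, labels=labels)
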