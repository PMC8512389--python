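"""Cleaning and segmentation of raw inertial recordings.

The preprocessing chain for wearable-sensor signals: mean imputation of
missing samples, a median filter, a 3rd-order low-pass Butterworth filter
with a 20 Hz corner (applied forward-backward, so zero phase), and
fixed-width sliding-window segmentation (default 2.56 s, 50% overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "Recording",
    "WindowSpec",
    "Window",
    "impute_missing",
    "median_filter",
    "lowpass_filter",
    "segment",
    "preprocess",
]


@dataclass
class Recording:
    """Multi-channel sensor recording sampled at a constant rate.

    channels maps channel name -> 1-D sample array (all equal length);
    labels, if present, give a per-sample class identifier.
    """

    channels: dict[str, np.ndarray]
    fs: float
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channels:
            raise ValueError("at least one channel required")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.n_samples:
                raise ValueError("labels length != channel length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels.keys())


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry. Defaults: 2.56 s windows, 50% overlap."""

    width_s: float = 2.56
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.width_s <= 0:
            raise ValueError("width_s must be positive")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must lie in [0, 1)")

    def width_samples(self, fs: float) -> int:
        w = int(round(self.width_s * fs))
        if w < 2:
            raise ValueError(f"window of {w} samples too short (need >= 2)")
        return w

    def stride(self, fs: float) -> int:
        s = int(round(self.width_samples(fs) * (1.0 - self.overlap_fraction)))
        return max(s, 1)


@dataclass
class Window:
    """One segmented window: per-channel samples plus a majority label."""

    start: int  # 0-based sample offset, half-open [start, start + width)
    samples: dict[str, np.ndarray]
    label: object | None = None


def impute_missing(series: np.ndarray) -> np.ndarray:
    """Replace NaN gaps with the mean of the available samples."""
    x = np.asarray(series, dtype=float).copy()
    missing = np.isnan(x)
    if missing.all():
        raise ValueError("cannot impute an all-missing series")
    if missing.any():
        x[missing] = x[~missing].mean()
    return x


def median_filter(series: np.ndarray, width: int = 3) -> np.ndarray:
    """Running median with edge replication; width must be odd."""
    if width < 1 or width % 2 == 0:
        raise ValueError(f"median filter width must be odd and >= 1, got {width}")
    x = np.asarray(series, dtype=float)
    if width == 1:
        return x.copy()
    return ndimage.median_filter(x, size=width, mode="nearest")


def lowpass_filter(
    series: np.ndarray, fs: float, corner_hz: float = 20.0, order: int = 3
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass; unit DC gain."""
    if corner_hz >= fs / 2:
        raise ValueError(f"corner {corner_hz} Hz >= Nyquist {fs / 2} Hz")
    sos = signal.butter(order, corner_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(series, dtype=float))


def butter_response(fs: float, freqs_hz, corner_hz: float = 20.0, order: int = 3) -> np.ndarray:
    """Single-pass magnitude response of the designed filter at freqs_hz."""
    sos = signal.butter(order, corner_hz, btype="low", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=2 * np.pi * np.atleast_1d(freqs_hz) / fs)
    return np.abs(h)


def _majority_label(labels: np.ndarray) -> object:
    # majority vote; ties broken toward the label occurring earliest
    values, first_pos = [], {}
    for i, v in enumerate(labels):
        if v not in first_pos:
            first_pos[v] = i
            values.append(v)
    counts = {v: int(np.sum(labels == v)) for v in values}
    best = max(counts.values())
    winners = [v for v in values if counts[v] == best]
    return min(winners, key=lambda v: first_pos[v])


def segment(recording: Recording, spec: WindowSpec) -> list[Window]:
    """Cut the recording into fully-contained sliding windows.

    Windows start at 0, stride, 2*stride, ...; a recording shorter than
    one window yields an empty list (with a warning), never an error.
    """
    w = spec.width_samples(recording.fs)
    stride = spec.stride(recording.fs)
    n = recording.n_samples
    if n < w:
        warnings.warn(
            f"recording of {n} samples shorter than window of {w}; no windows",
            stacklevel=2,
        )
        return []
    out = []
    for start in range(0, n - w + 1, stride):
        samples = {k: v[start : start + w] for k, v in recording.channels.items()}
        label = None
        if recording.labels is not None:
            label = _majority_label(recording.labels[start : start + w])
        out.append(Window(start=start, samples=samples, label=label))
    return out


def preprocess(
    recording: Recording,
    median_width: int = 3,
    corner_hz: float = 20.0,
    order: int = 3,
) -> Recording:
    """Impute, median-filter and low-pass every channel; labels unchanged."""
    cleaned = {}
    for name, series in recording.channels.items():
        x = impute_missing(series)
        x = median_filter(x, median_width)
        x = lowpass_filter(x, recording.fs, corner_hz=corner_hz, order=order)
        cleaned[name] = x
    return Recording(channels=cleaned, fs=recording.fs, labels=recording.labels)
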