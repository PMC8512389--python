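"""Time- and frequency-domain feature catalogue over signal windows.

Each window of each channel is summarized by the classic inertial-sensor
statistics (mean, variance, zero-crossing rate, IQR, spectral entropy,
crest factor, ...), plus pairwise features (Pearson correlation, cosine
distance) between channels of the same sensor.  Stacking the windows
gives the D-dimensional labeled feature matrix the selectors search over.

Degenerate-window conventions: any statistic with a zero denominator
(zero variance, zero RMS, all-zero spectrum) is defined as 0, so every
feature value is finite for finite input.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import FeatureMatrix
from .signal_prep import Recording, Window, WindowSpec, segment

__all__ = [
    "FeatureDef",
    "FeatureCatalog",
    "default_catalog",
    "time_features",
    "freq_features",
    "pair_features",
    "extract_matrix",
]

TIME_FEATURES = (
    "mean", "variance", "std", "abs_mean", "sra", "median", "mode", "min",
    "max", "peak_to_peak", "iqr", "rms", "zero_crossing_rate", "skewness",
    "kurtosis", "impulse_factor", "margin_factor", "shape_factor",
    "crest_factor",
)
FREQ_FEATURES = (
    "energy", "spectral_entropy", "freq_center", "rms_freq", "dc",
    "top1_freq", "top2_freq", "top3_freq", "spec_mean", "spec_std",
    "spec_skewness", "spec_kurtosis",
)
PAIR_FEATURES = ("correlation", "cosine_distance")


@dataclass(frozen=True)
class FeatureDef:
    """One catalogue entry: a named statistic with its arity and domain."""

    name: str
    arity: str  # "single" or "pair"
    domain: str  # "time" or "freq"


class FeatureCatalog:
    """Ordered, name-unique collection of feature definitions.

    Column order of the extracted matrix follows catalogue order, then
    sorted channel (or channel-pair) order, so it is stable across runs
    and independent of channel insertion order.
    """

    def __init__(self, definitions: list[FeatureDef]):
        names = [d.name for d in definitions]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        self.definitions = list(definitions)

    def __len__(self) -> int:
        return len(self.definitions)

    def __iter__(self):
        return iter(self.definitions)

    @property
    def single(self) -> list[FeatureDef]:
        return [d for d in self.definitions if d.arity == "single"]

    @property
    def pair(self) -> list[FeatureDef]:
        return [d for d in self.definitions if d.arity == "pair"]

    def subset(self, names: list[str]) -> "FeatureCatalog":
        by_name = {d.name: d for d in self.definitions}
        return FeatureCatalog([by_name[n] for n in names])


def default_catalog() -> FeatureCatalog:
    defs = [FeatureDef(n, "single", "time") for n in TIME_FEATURES]
    defs += [FeatureDef(n, "single", "freq") for n in FREQ_FEATURES]
    defs += [FeatureDef(n, "pair", "time") for n in PAIR_FEATURES]
    return FeatureCatalog(defs)


def _safe_div(num: float, den: float) -> float:
    return float(num / den) if den != 0 else 0.0


def time_features(window: np.ndarray) -> dict[str, float]:
    """Time-domain statistics of one window (length >= 2)."""
    x = np.asarray(window, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("window must hold at least 2 samples")
    mean = float(x.mean())
    var = float(x.var())  # 1/N normalization
    std = float(x.std(ddof=1))
    abs_mean = float(np.abs(x).mean())
    sra = float(np.sqrt(np.abs(x)).mean() ** 2)  # square-root amplitude
    q25, q75 = np.percentile(x, [25, 75], method="weibull")  # (n+1)-based rule
    rms = float(np.sqrt(np.mean(x**2)))
    sgn = np.sign(x)
    zcr = float(np.abs(np.diff(sgn)).sum() / (2 * n))
    if var > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, bias=True, fisher=False))
    else:
        skew = kurt = 0.0
    peak = float(np.abs(x).max())
    return {
        "mean": mean,
        "variance": var,
        "std": std,
        "abs_mean": abs_mean,
        "sra": sra,
        "median": float(np.median(x)),
        "mode": float(stats.mode(x, keepdims=False).mode),
        "min": float(x.min()),
        "max": float(x.max()),
        "peak_to_peak": float(x.max() - x.min()),
        "iqr": float(q75 - q25),
        "rms": rms,
        "zero_crossing_rate": zcr,
        "skewness": skew,
        "kurtosis": kurt,
        "impulse_factor": _safe_div(peak, abs_mean),
        "margin_factor": _safe_div(peak, sra),
        "shape_factor": _safe_div(rms, abs_mean),
        "crest_factor": _safe_div(peak, rms),
    }


def freq_features(window: np.ndarray, fs: float) -> dict[str, float]:
    """Spectral statistics of one window (length >= 4).

    The DC bin is reported separately; entropy, frequency center, RMS
    frequency, peak frequencies and the spectral-shape moments are
    computed over the non-DC half-spectrum (power weights p_k are the
    normalized squared magnitudes).
    """
    x = np.asarray(window, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("window must hold at least 4 samples")
    spectrum = np.fft.rfft(x)
    mag = np.abs(spectrum)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    energy = float(np.sum(x**2))
    dc = float(mag[0] / n)

    power = mag[1:] ** 2
    total = power.sum()
    out = {"energy": energy, "dc": dc}
    if total > 0:
        p = power / total
        nz = p[p > 0]
        out["spectral_entropy"] = float(-(nz * np.log2(nz)).sum())
        out["freq_center"] = float((freqs[1:] * p).sum())
        out["rms_freq"] = float(np.sqrt((freqs[1:] ** 2 * p).sum()))
        top = np.argsort(power)[::-1][:3]
        for i in range(3):
            out[f"top{i + 1}_freq"] = float(freqs[1:][top[i]]) if i < top.size else 0.0
    else:
        for name in ("spectral_entropy", "freq_center", "rms_freq",
                     "top1_freq", "top2_freq", "top3_freq"):
            out[name] = 0.0
    m = mag[1:]
    out["spec_mean"] = float(m.mean())
    out["spec_std"] = float(m.std())
    if m.var() > 0:
        out["spec_skewness"] = float(stats.skew(m, bias=True))
        out["spec_kurtosis"] = float(stats.kurtosis(m, bias=True, fisher=False))
    else:
        out["spec_skewness"] = 0.0
        out["spec_kurtosis"] = 0.0
    return out


def pair_features(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """Similarity between two equal-length channels of one window."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("pair features need two equal-length windows (>= 2 samples)")
    if a.std() == 0 or b.std() == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(a, b)[0, 1])
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    cos = 1.0 - _safe_div(float(a @ b), float(na * nb)) if na > 0 and nb > 0 else 0.0
    return {"correlation": corr, "cosine_distance": cos}


def _sensor_groups(channel_names: list[str]) -> list[list[str]]:
    # axes of one sensor share a name prefix, e.g. ax/ay/az, gx/gy/gz
    groups: dict[str, list[str]] = {}
    for name in channel_names:
        key = name[:-1] if len(name) > 1 else name
        groups.setdefault(key, []).append(name)
    return [sorted(v) for _, v in sorted(groups.items()) if len(v) > 1]


def _column_names(catalog: FeatureCatalog, channels: list[str], pairs) -> list[str]:
    names = []
    for d in catalog.single:
        for ch in channels:
            names.append(f"{d.name}__{ch}")
    for d in catalog.pair:
        for a, b in pairs:
            names.append(f"{d.name}__{a}_{b}")
    return names


def extract_matrix(
    recording: Recording,
    catalog: FeatureCatalog | None = None,
    windowspec: WindowSpec | None = None,
    pair_scope: str = "sensor",
) -> FeatureMatrix:
    """Segment a recording and compute the feature matrix.

    pair_scope: "sensor" computes pair features within each 3-axis sensor
    group (inferred from channel-name prefixes); "all" over every channel
    pair; "none" skips them.  D = (#single features x #channels) +
    (#pair features x #pairs).
    """
    catalog = catalog or default_catalog()
    windowspec = windowspec or WindowSpec()
    channels = sorted(recording.channel_names)
    if pair_scope == "sensor":
        pairs = [p for g in _sensor_groups(channels) for p in itertools.combinations(g, 2)]
    elif pair_scope == "all":
        pairs = list(itertools.combinations(channels, 2))
    elif pair_scope == "none":
        pairs = []
    else:
        raise ValueError(f"unknown pair_scope {pair_scope!r}")
    columns = _column_names(catalog, channels, pairs)

    windows = segment(recording, windowspec)
    rows = np.empty((len(windows), len(columns)))
    labels = []
    for i, w in enumerate(windows):
        rows[i] = _window_row(w, catalog, channels, pairs, recording.fs)
        labels.append(w.label if w.label is not None else 0)
    frame = pd.DataFrame(rows, columns=columns)
    return FeatureMatrix(frame, np.asarray(labels))


def _window_row(
    w: Window,
    catalog: FeatureCatalog,
    channels: list[str],
    pairs: list[tuple[str, str]],
    fs: float,
) -> np.ndarray:
    per_channel: dict[str, dict[str, float]] = {}
    need_time = any(d.domain == "time" for d in catalog.single)
    need_freq = any(d.domain == "freq" for d in catalog.single)
    for ch in channels:
        vals: dict[str, float] = {}
        if need_time:
            vals.update(time_features(w.samples[ch]))
        if need_freq:
            vals.update(freq_features(w.samples[ch], fs))
        per_channel[ch] = vals
    row = [per_channel[ch][d.name] for d in catalog.single for ch in channels]
    if catalog.pair and pairs:
        per_pair = {p: pair_features(w.samples[p[0]], w.samples[p[1]]) for p in pairs}
        row += [per_pair[p][d.name] for d in catalog.pair for p in pairs]
    return np.asarray(row)
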