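"""Synthetic data with planted ground truth.

Two generators make the whole pipeline testable without downloads:

* :func:`gen_feature_table` plants a feature table in which a known subset
  of columns is informative (class-conditional mean shifts), another subset
  is redundant (noisy copies of informative columns with a controlled
  correlation), and the remainder is label-independent noise.  This mirrors
  the premise of wrapper feature selection: features split into relevant,
  redundant, and irrelevant.
* :func:`gen_recording` emits IMU-like 6-channel recordings.  Dynamic
  activities differ by their dominant oscillation band; stationary
  activities (zero oscillation amplitude) differ only through the
  accelerometer's orientation relative to gravity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import FeatureMatrix
from .signal_prep import Recording

__all__ = [
    "PlantedFeatureSpec",
    "ClassSignalSpec",
    "SyntheticRecordingSpec",
    "gen_feature_table",
    "gen_recording",
    "GRAVITY",
]

GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class PlantedFeatureSpec:
    """Parameters of the planted feature table.

    effect_size is the class-mean separation of adjacent classes in units
    of the per-feature noise SD; redundancy_corr is the target Pearson
    correlation between a redundant column and its informative parent.
    """

    n_samples: int = 600
    n_classes: int = 4
    n_informative: int = 10
    n_redundant: int = 5
    n_noise: int = 85
    effect_size: float = 1.5
    redundancy_corr: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_informative < 1:
            raise ValueError("need at least 1 informative feature")
        if self.n_redundant < 0 or self.n_noise < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_samples < 2 * self.n_classes:
            raise ValueError("every class needs at least 2 samples")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive (no signal to recover)")
        if not (0 < self.redundancy_corr <= 1):
            raise ValueError("redundancy_corr must lie in (0, 1]")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


def _balanced_labels(n_samples: int, n_classes: int, rng: np.random.Generator) -> np.ndarray:
    # block-wise assignment, then a seeded shuffle: balanced within +/-1
    base = np.arange(n_samples) % n_classes
    base.sort()
    rng.shuffle(base)
    return base


def gen_feature_table(spec: PlantedFeatureSpec) -> tuple[FeatureMatrix, set[int]]:
    """Generate the planted table; returns (matrix, informative index set).

    Column order is shuffled with the seed so the truth set is not a
    positional prefix; the returned indices refer to the shuffled order.
    """
    rng = np.random.default_rng(spec.seed)
    y = _balanced_labels(spec.n_samples, spec.n_classes, rng)

    cols: list[np.ndarray] = []
    # informative: per-feature class means on an effect_size-spaced grid,
    # permuted across classes, plus unit noise
    grid = (np.arange(spec.n_classes) - (spec.n_classes - 1) / 2.0) * spec.effect_size
    informative = []
    for _ in range(spec.n_informative):
        means = rng.permutation(grid)
        x = means[y] + rng.standard_normal(spec.n_samples)
        informative.append(x)
        cols.append(x)
    # redundant: rho * standardized parent + sqrt(1 - rho^2) * fresh noise
    rho = spec.redundancy_corr
    for j in range(spec.n_redundant):
        parent = informative[j % spec.n_informative]
        z = (parent - parent.mean()) / parent.std()
        cols.append(rho * z + np.sqrt(1.0 - rho**2) * rng.standard_normal(spec.n_samples))
    for _ in range(spec.n_noise):
        cols.append(rng.standard_normal(spec.n_samples))

    order = rng.permutation(spec.n_features)
    data = np.column_stack(cols)[:, order]
    truth = {int(np.flatnonzero(order == j)[0]) for j in range(spec.n_informative)}
    names = [f"f{i:03d}" for i in range(spec.n_features)]
    frame = pd.DataFrame(data, columns=names)
    return FeatureMatrix(frame, y), truth


@dataclass(frozen=True)
class ClassSignalSpec:
    """One activity class of a synthetic recording."""

    label: str
    band_hz: tuple[float, float]  # dominant oscillation band (lo, hi)
    amplitude: float  # 0 => stationary activity
    orientation: tuple[float, float, float]  # unit gravity direction
    noise_sd: float = 0.2


@dataclass(frozen=True)
class SyntheticRecordingSpec:
    fs: float = 50.0
    duration_s: float = 10.0  # per class segment
    classes: Sequence[ClassSignalSpec] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not self.classes:
            raise ValueError("at least one class required")
        for c in self.classes:
            if not (0 <= c.band_hz[0] <= c.band_hz[1]):
                raise ValueError(f"invalid band {c.band_hz}")
            if c.band_hz[1] >= self.fs / 2:
                raise ValueError(
                    f"band {c.band_hz} reaches the Nyquist frequency {self.fs / 2}"
                )
            v = np.asarray(c.orientation, dtype=float)
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-6):
                raise ValueError(f"orientation {c.orientation} is not unit-norm")


def gen_recording(spec: SyntheticRecordingSpec) -> Recording:
    """Synthesize a 6-channel IMU recording with per-sample labels.

    Accelerometer axes = gravity * orientation + sinusoid + Gaussian noise;
    gyroscope axes = sinusoid + noise.  Each class occupies one contiguous
    segment of fs * duration_s samples.
    """
    rng = np.random.default_rng(spec.seed)
    n_per = int(round(spec.fs * spec.duration_s))
    segments = {name: [] for name in ("ax", "ay", "az", "gx", "gy", "gz")}
    labels: list[np.ndarray] = []
    t_local = np.arange(n_per) / spec.fs
    for c in spec.classes:
        orient = np.asarray(c.orientation, dtype=float)
        for axis, name in enumerate(("ax", "ay", "az")):
            osc = _sinusoid(c, t_local, rng)
            segments[name].append(
                GRAVITY * orient[axis] + osc + rng.normal(0.0, c.noise_sd, n_per)
            )
        for name in ("gx", "gy", "gz"):
            osc = _sinusoid(c, t_local, rng)
            segments[name].append(osc + rng.normal(0.0, c.noise_sd, n_per))
        labels.append(np.full(n_per, c.label, dtype=object))
    channels = {name: np.concatenate(parts) for name, parts in segments.items()}
    return Recording(channels=channels, fs=spec.fs, labels=np.concatenate(labels))


def _sinusoid(c: ClassSignalSpec, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if c.amplitude == 0:
        return np.zeros_like(t)
    f = rng.uniform(*c.band_hz)
    phase = rng.uniform(0.0, 2 * np.pi)
    return c.amplitude * np.sin(2 * np.pi * f * t + phase)
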