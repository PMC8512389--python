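"""Structured run reports shared by every search algorithm.

A RunReport captures everything needed to replay a run (config echo and
seeds), the per-iteration convergence history, and the final mask both as
a bit-string and as a sorted 0-based index list.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import bitstring_to_mask, mask_indices, mask_to_bitstring
from .evaluation import FitnessResult

__all__ = ["HistoryEntry", "RunReport"]


@dataclass
class HistoryEntry:
    iteration: int
    n_evaluations: int
    best_fitness: float
    n_selected: int
    wall_time_s: float = 0.0


@dataclass
class RunReport:
    algo: str
    config: dict
    seed: int
    best_mask: str  # bit-string
    best_fitness: float
    best_n_selected: int
    evaluator_id: str = ""
    history: list[HistoryEntry] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @property
    def best_indices(self) -> list[int]:
        return mask_indices(bitstring_to_mask(self.best_mask))

    @property
    def mask_array(self) -> np.ndarray:
        return bitstring_to_mask(self.best_mask)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["best_indices"] = self.best_indices
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_dict(cls, d: dict) -> "RunReport":
        d = dict(d)
        d.pop("best_indices", None)
        d["history"] = [HistoryEntry(**h) for h in d.get("history", [])]
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunReport":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_result(cls, algo: str, config: dict, seed: int, mask: np.ndarray,
                    fitness: FitnessResult, history: list[HistoryEntry],
                    extras: dict | None = None) -> "RunReport":
        return cls(
            algo=algo, config=config, seed=seed,
            best_mask=mask_to_bitstring(mask),
            best_fitness=fitness.accuracy,
            best_n_selected=fitness.n_selected,
            evaluator_id=fitness.evaluator_id,
            history=history, extras=extras or {},
        )
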