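"""Bee-swarm optimization over binary feature masks.

The outer search keeps a reference solution from which a search region of
`nb` candidate masks is spawned by three bit-flip strategies; each bee
runs a local search (hill climbing, tabular Q, or deep Q) from its
candidate and posts its best find to the dance table.  The next reference
solution comes from the dance table: a global improvement resets the
chance counter (intensification around the new best); otherwise chances
are consumed one per iteration, and when they run out the search
diversifies to the spawned candidate furthest (Hamming) from the best
global solution that is not tabu.  Past reference solutions live in a
tabu list so the search never cycles through them.

The chance counter deliberately persists across iterations and is reset
only on global improvement or diversification; resetting it every
iteration would make diversification unreachable.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np

from .core import hamming
from .evaluation import FitnessResult, better
from .report import HistoryEntry, RunReport
from .rl import QLearnParams, RewardParams, make_local_search

__all__ = ["BSOConfig", "BSOState", "generate_search_region",
           "hill_climb_local_search", "advance_reference", "run_bso"]


@dataclass(frozen=True)
class BSOConfig:
    """Outer-search settings. Defaults: nb=10 bees, flip=5, max_chances=3."""

    nb: int = 10
    flip: int = 5
    max_chances: int = 3
    max_iter: int = 50
    local_search: str = "deep-q"  # "hill" | "tabular-q" | "deep-q"
    local_budget: int = 20  # agent steps (or neighbor evaluations) per bee
    patience: int | None = None  # optional no-improvement early stop
    seed: int = 0
    qlearn: QLearnParams = field(default_factory=QLearnParams)
    reward: RewardParams = field(default_factory=RewardParams)

    def __post_init__(self) -> None:
        if self.nb < 1 or self.flip < 1 or self.max_chances < 1:
            raise ValueError("nb, flip and max_chances must be positive")
        if self.max_iter < 1 or self.local_budget < 1:
            raise ValueError("max_iter and local_budget must be positive")
        if self.local_search not in {"hill", "tabular-q", "deep-q"}:
            raise ValueError(f"unknown local_search {self.local_search!r}")


@dataclass
class BSOState:
    """Mutable search state threaded through the iterations."""

    ref_sol: np.ndarray
    best_global_sol: np.ndarray
    best_global_fit: FitnessResult
    dance: list[tuple[np.ndarray, FitnessResult]] = field(default_factory=list)
    tabu: list[bytes] = field(default_factory=list)  # reference masks seen
    n_chances: int = 0
    candidates: list[np.ndarray] = field(default_factory=list)

    def in_tabu(self, mask: np.ndarray) -> bool:
        return np.asarray(mask).astype(np.uint8).tobytes() in self.tabu

    def push_tabu(self, mask: np.ndarray) -> None:
        key = np.asarray(mask).astype(np.uint8).tobytes()
        if key not in self.tabu:
            self.tabu.append(key)


def _random_mask(n: int, rng: np.random.Generator) -> np.ndarray:
    mask = (rng.random(n) < 0.5).astype(np.uint8)
    if mask.sum() == 0:
        mask[rng.integers(n)] = 1
    return mask


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if mask.sum() == 0:
        mask[rng.integers(mask.shape[0])] = 1
    return mask


def generate_search_region(ref: np.ndarray, config: BSOConfig,
                           rng: np.random.Generator | None = None
                           ) -> list[np.ndarray]:
    """Spawn the nb candidate masks around a reference solution.

    Strategy 1 (first min(flip, nb) masks): mask i flips positions
    i, i+flip, i+2*flip, ...  Strategy 2 (next masks): the k-th flips the
    contiguous block of ceil(N/flip) bits starting at k*ceil(N/flip).
    Strategy 3 (remainder): ceil(N/flip) seeded-random distinct positions.
    All-zero results are repaired with one random bit; duplicates of the
    reference or of each other are re-randomized.
    """
    ref = np.asarray(ref).astype(np.uint8)
    n = ref.shape[0]
    if config.flip > n:
        raise ValueError(f"flip={config.flip} exceeds mask length {n}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    block = math.ceil(n / config.flip)

    def random_flip() -> np.ndarray:
        mask = ref.copy()
        positions = rng.choice(n, size=min(block, n), replace=False)
        mask[positions] ^= 1
        return mask

    masks: list[np.ndarray] = []
    for i in range(config.nb):
        mask = ref.copy()
        if i < min(config.flip, config.nb):
            mask[np.arange(i, n, config.flip)] ^= 1
        elif i < min(2 * config.flip, config.nb):
            k = i - config.flip
            start = k * block
            if start >= n:
                mask = random_flip()
            else:
                mask[start : min(start + block, n)] ^= 1
        else:
            mask = random_flip()
        masks.append(_repair(mask, rng))

    # re-randomize any duplicate of the reference or of an earlier mask
    seen = {ref.tobytes()}
    for i, mask in enumerate(masks):
        attempts = 0
        while mask.tobytes() in seen and attempts < 100:
            mask = _repair(random_flip(), rng)
            attempts += 1
        masks[i] = mask
        seen.add(mask.tobytes())
    return masks


def hill_climb_local_search(start: np.ndarray, budget: int, evaluate,
                            seed: int = 0) -> tuple[np.ndarray, FitnessResult]:
    """Best-improvement bit-flip hill climbing; never worse than start.

    budget counts neighbor evaluations; budget 0 returns the start.
    """
    from .rl import HillClimbLocalSearch

    start = np.asarray(start).astype(np.uint8)
    if budget == 0:
        return start.copy(), evaluate(start)
    searcher = HillClimbLocalSearch(start.shape[0], seed=seed)
    return searcher.run(start, start, evaluate, budget)


def advance_reference(state: BSOState, config: BSOConfig,
                      rng: np.random.Generator) -> BSOState:
    """Pick the next reference solution from the populated dance table."""
    if not state.dance:
        raise ValueError("dance table is empty; run the bees first")
    best_sol, best_fit = state.dance[0]
    for mask, fit in state.dance[1:]:
        if better(fit, best_fit):
            best_sol, best_fit = mask, fit

    if better(best_fit, state.best_global_fit):
        state.best_global_sol = best_sol.copy()
        state.best_global_fit = best_fit
        state.n_chances = config.max_chances
        new_ref = best_sol.copy()
    else:
        state.n_chances -= 1
        if state.n_chances > 0:
            new_ref = best_sol.copy()  # intensify around the iteration's best
        else:
            new_ref = _furthest_fresh(state, rng)
            state.n_chances = config.max_chances

    if state.in_tabu(new_ref):
        # keep reference solutions unique within a run
        new_ref = _furthest_fresh(state, rng)
        state.n_chances = config.max_chances
    state.ref_sol = new_ref
    state.push_tabu(new_ref)
    return state


def _furthest_fresh(state: BSOState, rng: np.random.Generator) -> np.ndarray:
    """Diversification target: the spawned candidate furthest from the best
    global solution among those not in tabu; seeded random fallback."""
    fresh = [c for c in state.candidates if not state.in_tabu(c)]
    n = state.best_global_sol.shape[0]
    if not fresh:
        for _ in range(100):
            mask = _random_mask(n, rng)
            if not state.in_tabu(mask):
                return mask
        return _random_mask(n, rng)
    dists = [hamming(c, state.best_global_sol) for c in fresh]
    return fresh[int(np.argmax(dists))].copy()


def run_bso(objective, config: BSOConfig | None = None,
            algo_name: str = "bso") -> RunReport:
    """Run the full outer search; deterministic under a fixed seed.

    `objective` maps a mask to a FitnessResult (see
    :class:`~baroque.evaluation.MaskObjective`); its ``n_features``
    attribute fixes the mask length.
    """
    config = config or BSOConfig()
    rng = np.random.default_rng(config.seed)
    n = objective.n_features
    t0 = time.perf_counter()

    searcher = make_local_search(config.local_search, n, config.qlearn,
                                 config.reward, seed=config.seed + 1)
    ref = _random_mask(n, rng)
    ref_fit = objective(ref)
    state = BSOState(ref_sol=ref, best_global_sol=ref.copy(),
                     best_global_fit=ref_fit, n_chances=config.max_chances)
    state.push_tabu(ref)

    history: list[HistoryEntry] = []
    since_improvement = 0
    for iteration in range(config.max_iter):
        state.candidates = generate_search_region(state.ref_sol, config, rng)
        state.dance = []
        for candidate in state.candidates:
            mask, fit = searcher.run(candidate, state.best_global_sol,
                                     objective, config.local_budget)
            state.dance.append((mask, fit))
        prev_best = state.best_global_fit
        advance_reference(state, config, rng)
        improved = better(state.best_global_fit, prev_best)
        since_improvement = 0 if improved else since_improvement + 1
        history.append(HistoryEntry(
            iteration=iteration,
            n_evaluations=objective.n_evaluations,
            best_fitness=state.best_global_fit.accuracy,
            n_selected=state.best_global_fit.n_selected,
            wall_time_s=time.perf_counter() - t0,
        ))
        if config.patience is not None and since_improvement >= config.patience:
            break

    config_echo = {
        "nb": config.nb, "flip": config.flip,
        "max_chances": config.max_chances, "max_iter": config.max_iter,
        "local_search": config.local_search,
        "local_budget": config.local_budget,
    }
    return RunReport.from_result(algo_name, config_echo, config.seed,
                                 state.best_global_sol, state.best_global_fit,
                                 history)
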