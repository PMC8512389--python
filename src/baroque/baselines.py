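"""Swarm-intelligence comparators sharing the mask objective.

Minimal textbook variants: a real-coded genetic algorithm with tournament
selection and a 0.5 decode threshold, a global-best binary PSO with a
sigmoid velocity transfer, and a pheromone-ratio ant system.  Settings
follow the usual HAR comparison configuration: GA threshold/crossover/
mutation = 0.5/0.8/0.01; BPSO threshold/inertia/acceleration = 0.5/0.9/
2,2; ACO ants/initial pheromone/deposit/retention = 10/1/0.1/0.95.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .evaluation import FitnessResult, better
from .report import HistoryEntry, RunReport

__all__ = ["GAConfig", "BPSOConfig", "ACOConfig",
           "decode_threshold", "run_ga", "run_bpso", "run_aco"]


@dataclass(frozen=True)
class GAConfig:
    population: int = 20
    generations: int = 50
    threshold: float = 0.5
    crossover_rate: float = 0.8
    mutation_rate: float = 0.01
    tournament: int = 2
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must hold at least 2 genomes")
        for r in (self.threshold, self.crossover_rate, self.mutation_rate):
            if not (0 <= r <= 1):
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class BPSOConfig:
    swarm: int = 20
    iterations: int = 50
    threshold: float = 0.5
    inertia: float = 0.9
    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.inertia <= 1):
            raise ValueError("inertia must lie in (0, 1]")


@dataclass(frozen=True)
class ACOConfig:
    n_ants: int = 10
    iterations: int = 50
    tau0: float = 1.0
    deposit: float = 0.1
    retention: float = 0.95  # fraction of pheromone kept per iteration
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau0 <= 0 or self.deposit <= 0:
            raise ValueError("pheromone amounts must be positive")
        if not (0 < self.retention <= 1):
            raise ValueError("retention must lie in (0, 1]")


def decode_threshold(genome: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Real genome in [0,1]^N -> mask: gene > threshold selects the feature."""
    return (np.asarray(genome, dtype=float) > threshold).astype(np.uint8)


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if mask.sum() == 0:
        mask = mask.copy()
        mask[rng.integers(mask.shape[0])] = 1
    return mask


def _mask_fit(objective, mask: np.ndarray, rng: np.random.Generator
              ) -> tuple[np.ndarray, FitnessResult]:
    mask = _repair(mask, rng)
    return mask, objective(mask)


def run_ga(objective, config: GAConfig | None = None) -> RunReport:
    """Genetic algorithm: tournament selection (size 2), uniform crossover,
    per-gene mutation, elitism of 1; best mask by the shared tie-break."""
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    n = objective.n_features
    t0 = time.perf_counter()
    pop = rng.random((config.population, n))

    def score(genome):
        return _mask_fit(objective, decode_threshold(genome, config.threshold), rng)

    scored = [score(g) for g in pop]
    best_mask, best_fit = scored[0]
    for m, f in scored[1:]:
        if better(f, best_fit):
            best_mask, best_fit = m, f
    history = []
    for gen in range(config.generations):
        fits = [f for _, f in scored]
        elite_idx = _argbest(fits)
        new_pop = [pop[elite_idx].copy() for _ in range(config.elitism)]
        while len(new_pop) < config.population:
            pa = _tournament(pop, fits, config.tournament, rng)
            pb = _tournament(pop, fits, config.tournament, rng)
            child = pa.copy()
            if rng.random() < config.crossover_rate:
                take = rng.random(n) < 0.5
                child = np.where(take, pa, pb)
            mutate = rng.random(n) < config.mutation_rate
            child = np.where(mutate, rng.random(n), child)
            new_pop.append(child)
        pop = np.array(new_pop)
        scored = [score(g) for g in pop]
        for m, f in scored:
            if better(f, best_fit):
                best_mask, best_fit = m, f
        history.append(HistoryEntry(gen, objective.n_evaluations,
                                    best_fit.accuracy, best_fit.n_selected,
                                    time.perf_counter() - t0))
    cfg = {"population": config.population, "generations": config.generations,
           "threshold": config.threshold, "crossover_rate": config.crossover_rate,
           "mutation_rate": config.mutation_rate}
    return RunReport.from_result("ga", cfg, config.seed, best_mask, best_fit,
                                 history)


def _argbest(fits: list[FitnessResult]) -> int:
    best = 0
    for i in range(1, len(fits)):
        if better(fits[i], fits[best]):
            best = i
    return best


def _tournament(pop, fits, size, rng) -> np.ndarray:
    idx = rng.integers(len(pop), size=size)
    winner = idx[0]
    for i in idx[1:]:
        if better(fits[i], fits[winner]):
            winner = i
    return pop[winner]


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def bpso_transfer(v, u=0.5):
    """Sigmoid transfer of velocity to a binary position.

    Selects where sigmoid(v) >= u; u is a uniform draw during the search
    and defaults to the 0.5 threshold, so the exact boundary (zero
    velocity, sigmoid(0) = 0.5) resolves as "select".
    """
    return (_sigmoid(np.asarray(v, dtype=float)) >= u).astype(np.uint8)


def run_bpso(objective, config: BPSOConfig | None = None) -> RunReport:
    """Binary PSO, global-best topology.  Positions are re-sampled through
    the sigmoid transfer of velocity (select where sigmoid(v) >= u,
    u ~ U(0,1); ties at the threshold resolve as "select")."""
    config = config or BPSOConfig()
    rng = np.random.default_rng(config.seed)
    n = objective.n_features
    t0 = time.perf_counter()
    v = rng.uniform(-1, 1, size=(config.swarm, n))
    x = (rng.random((config.swarm, n)) < 0.5).astype(np.uint8)

    def evaluate(row):
        return _mask_fit(objective, row.astype(np.uint8), rng)

    pbest, pfit = [], []
    for i in range(config.swarm):
        m, f = evaluate(x[i])
        x[i] = m
        pbest.append(m.copy())
        pfit.append(f)
    g = _argbest(pfit)
    gbest, gfit = pbest[g].copy(), pfit[g]
    history = []
    for it in range(config.iterations):
        for i in range(config.swarm):
            r1, r2 = rng.random(n), rng.random(n)
            xi = x[i].astype(float)
            v[i] = (config.inertia * v[i]
                    + config.c1 * r1 * (pbest[i].astype(float) - xi)
                    + config.c2 * r2 * (gbest.astype(float) - xi))
            np.clip(v[i], -config.v_max, config.v_max, out=v[i])
            x[i] = bpso_transfer(v[i], rng.random(n))
            m, f = evaluate(x[i])
            x[i] = m
            if better(f, pfit[i]):
                pbest[i], pfit[i] = m.copy(), f
            if better(f, gfit):
                gbest, gfit = m.copy(), f
        history.append(HistoryEntry(it, objective.n_evaluations,
                                    gfit.accuracy, gfit.n_selected,
                                    time.perf_counter() - t0))
    cfg = {"swarm": config.swarm, "iterations": config.iterations,
           "threshold": config.threshold, "inertia": config.inertia,
           "c1": config.c1, "c2": config.c2}
    return RunReport.from_result("bpso", cfg, config.seed, gbest, gfit, history)


def run_aco(objective, config: ACOConfig | None = None) -> RunReport:
    """Ant system: feature j is included with probability tau_j /
    (tau_j + mean(tau)); pheromone decays by the retention factor and the
    iteration-best ant deposits on its selected features."""
    config = config or ACOConfig()
    rng = np.random.default_rng(config.seed)
    n = objective.n_features
    t0 = time.perf_counter()
    tau = np.full(n, config.tau0, dtype=float)
    best_mask, best_fit = None, None
    history = []
    for it in range(config.iterations):
        iter_best_mask, iter_best_fit = None, None
        for _ in range(config.n_ants):
            p = tau / (tau + tau.mean())
            mask = (rng.random(n) < p).astype(np.uint8)
            mask, fit = _mask_fit(objective, mask, rng)
            if iter_best_fit is None or better(fit, iter_best_fit):
                iter_best_mask, iter_best_fit = mask, fit
            if best_fit is None or better(fit, best_fit):
                best_mask, best_fit = mask.copy(), fit
        tau *= config.retention
        tau[iter_best_mask.astype(bool)] += config.deposit
        history.append(HistoryEntry(it, objective.n_evaluations,
                                    best_fit.accuracy, best_fit.n_selected,
                                    time.perf_counter() - t0))
    cfg = {"n_ants": config.n_ants, "iterations": config.iterations,
           "tau0": config.tau0, "deposit": config.deposit,
           "retention": config.retention}
    return RunReport.from_result("aco", cfg, config.seed, best_mask, best_fit,
                                 history, extras={"pheromone": tau.tolist()})
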