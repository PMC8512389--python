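"""High-level feature-selection entry points.

`select_features` runs one algorithm on a labeled feature matrix and
returns its RunReport; `compare` runs several under roughly matched
mask-evaluation budgets so their convergence can be tabulated side by
side.  Algorithms: "baroque" (bee swarm + deep-Q local search), "bso"
(bee swarm + hill climbing), "qbso" (bee swarm + tabular Q), "dqn"
(standalone deep-Q search), "ga", "bpso", "aco".
"""

from __future__ import annotations

import time
from dataclasses import replace

import numpy as np

from .baselines import ACOConfig, BPSOConfig, GAConfig, run_aco, run_bpso, run_ga
from .bso import BSOConfig, run_bso
from .core import FeatureMatrix
from .evaluation import EvaluatorSpec, MaskObjective, confusion_summary, evaluate_mask
from .report import HistoryEntry, RunReport
from .rl import DeepQLocalSearch, QLearnParams, RewardParams

__all__ = ["ALGORITHMS", "select_features", "compare", "run_dqn"]

ALGORITHMS = ("baroque", "bso", "qbso", "dqn", "ga", "bpso", "aco")

_LOCAL_SEARCH = {"baroque": "deep-q", "bso": "hill", "qbso": "tabular-q"}


def run_dqn(objective, budget: int, qlearn: QLearnParams | None = None,
            reward: RewardParams | None = None, seed: int = 0,
            n_episodes: int = 10) -> RunReport:
    """Standalone deep-Q search: one persistent learner, `n_episodes`
    episodes from the evolving best mask, `budget` agent steps in total.
    With no outer swarm the neighborhood restriction is degenerate, so
    all positions stay flippable."""
    qlearn = qlearn or QLearnParams()
    reward = reward or RewardParams()
    rng = np.random.default_rng(seed)
    n = objective.n_features
    searcher = DeepQLocalSearch(n, qlearn, reward, seed=seed)
    t0 = time.perf_counter()
    mask = (rng.random(n) < 0.5).astype(np.uint8)
    if mask.sum() == 0:
        mask[rng.integers(n)] = 1
    best_mask, best_fit = mask, None
    history = []
    per_episode = max(budget // n_episodes, 1)
    for episode in range(n_episodes):
        m, f = searcher.run(best_mask, best_mask, objective, per_episode)
        if best_fit is None or f.accuracy > best_fit.accuracy or (
                f.accuracy == best_fit.accuracy and f.n_selected < best_fit.n_selected):
            best_mask, best_fit = m, f
        history.append(HistoryEntry(episode, objective.n_evaluations,
                                    best_fit.accuracy, best_fit.n_selected,
                                    time.perf_counter() - t0))
    cfg = {"budget": budget, "n_episodes": n_episodes}
    return RunReport.from_result("dqn", cfg, seed, best_mask, best_fit, history)


def select_features(
    matrix: FeatureMatrix,
    algo: str = "baroque",
    evaluator: EvaluatorSpec | None = None,
    seed: int = 0,
    budget: int | None = None,
    bso_config: BSOConfig | None = None,
    ga_config: GAConfig | None = None,
    bpso_config: BPSOConfig | None = None,
    aco_config: ACOConfig | None = None,
) -> RunReport:
    """Run one selection algorithm on a feature matrix.

    `budget`, if given, approximately fixes the number of mask
    evaluations by adjusting each algorithm's iteration count.
    """
    if algo not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algo!r}; choose from {ALGORITHMS}")
    evaluator = evaluator or EvaluatorSpec()
    objective = MaskObjective(matrix, evaluator)

    if algo in _LOCAL_SEARCH:
        config = bso_config or BSOConfig(seed=seed)
        config = replace(config, local_search=_LOCAL_SEARCH[algo], seed=seed)
        if budget is not None:
            iters = max(budget // (config.nb * config.local_budget), 1)
            config = replace(config, max_iter=iters)
        report = run_bso(objective, config, algo_name=algo)
    elif algo == "dqn":
        report = run_dqn(objective, budget or 1000, seed=seed)
    elif algo == "ga":
        config = ga_config or GAConfig(seed=seed)
        config = replace(config, seed=seed)
        if budget is not None:
            config = replace(config, generations=max(budget // config.population, 1))
        report = run_ga(objective, config)
    elif algo == "bpso":
        config = bpso_config or BPSOConfig(seed=seed)
        config = replace(config, seed=seed)
        if budget is not None:
            config = replace(config, iterations=max(budget // config.swarm, 1))
        report = run_bpso(objective, config)
    else:  # aco
        config = aco_config or ACOConfig(seed=seed)
        config = replace(config, seed=seed)
        if budget is not None:
            config = replace(config, iterations=max(budget // config.n_ants, 1))
        report = run_aco(objective, config)

    report.evaluator_id = evaluator.evaluator_id
    report.extras["n_evaluations"] = objective.n_evaluations
    report.extras["n_queries"] = objective.n_queries
    report.extras["confusion"] = _final_confusion(matrix, report.mask_array,
                                                  evaluator)
    return report


def _final_confusion(matrix, mask, spec: EvaluatorSpec) -> dict:
    from sklearn.model_selection import train_test_split

    from .evaluation import _make_classifier

    if spec.protocol != "holdout":
        return {}
    x = matrix.values(mask)
    y = matrix.labels
    xtr, xte, ytr, yte = train_test_split(x, y, train_size=spec.train_fraction,
                                          random_state=spec.seed, stratify=y)
    clf = _make_classifier(spec).fit(xtr, ytr)
    return confusion_summary(yte, clf.predict(xte))


def compare(matrix: FeatureMatrix, algos=("baroque", "bso", "dqn"),
            evaluator: EvaluatorSpec | None = None, seed: int = 0,
            budget: int = 1000) -> dict[str, RunReport]:
    """Run several algorithms under a matched evaluation budget."""
    return {a: select_features(matrix, a, evaluator=evaluator, seed=seed,
                               budget=budget) for a in algos}
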