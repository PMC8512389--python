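"""Multi-agent Q-learning / deep-Q local search over feature masks.

Each feature owns an agent.  The agent for feature u observes a binary
vector of length 2N: a one-hot block first (entry u set iff feature u is
currently selected, all other entries 0), then the full selection mask.
Its two actions are "leave my bit" and "flip my bit".  Flips are
restricted to the positions where the current mask and the best global
mask differ (their XOR), which steers trajectories toward the incumbent;
when the two masks coincide the restriction degenerates and every
position is allowed.

The reward after a step compares consecutive accuracies: an increase pays
the new accuracy itself; a decrease is penalized by half the (negative)
accuracy change; a flat move pays +/- accuracy x design-factor, positive
exactly when the feature count went down — nudging ties toward smaller
subsets.

One value function is shared by all agents (the one-hot block is what
distinguishes them): a lookup table in tabular mode, or a single-hidden-
layer network with experience replay and a periodically copied target
network in deep mode.  Agents step sequentially in index order, sharing
the evolving mask.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from ._nn import QNetwork
from .evaluation import FitnessResult, better

__all__ = [
    "RewardParams",
    "QLearnParams",
    "Experience",
    "ReplayBuffer",
    "encode_observation",
    "allowed_flips",
    "compute_reward",
    "q_update",
    "replay_sample",
    "dqn_train_step",
    "TabularQLocalSearch",
    "DeepQLocalSearch",
    "make_local_search",
    "run_rl_local_search",
]


@dataclass(frozen=True)
class RewardParams:
    """penalty_coeff scales the punishment for accuracy drops (fixed 0.5);
    design_factor sets the magnitude of the equal-accuracy nudge."""

    penalty_coeff: float = 0.5
    design_factor: float = 0.1

    def __post_init__(self) -> None:
        if self.design_factor <= 0:
            raise ValueError("design_factor must be positive")


@dataclass(frozen=True)
class QLearnParams:
    """Learning hyper-parameters for both tabular and deep modes."""

    mode: str = "deep"  # "tabular" or "deep"
    alpha: float = 0.1  # tabular learning rate, in (0, 1]
    gamma: float = 0.9  # discount, in [0, 1)
    eps0: float = 1.0
    eps_min: float = 0.1
    eps_decay: float = 0.999  # multiplicative, per step
    hid_num: int = 64
    lr: float = 1e-3
    buffer_capacity: int = 10_000
    batch_size: int = 32
    target_copy_every: int = 50
    warmup: int = 64  # experiences before training starts (2 mini-batches)
    train_every: int = 1

    def __post_init__(self) -> None:
        if self.mode not in {"tabular", "deep"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if not (0 <= self.gamma < 1):
            raise ValueError("gamma must lie in [0, 1)")


@dataclass
class Experience:
    """One transition (s, a, r, s', T)."""

    s: np.ndarray
    a: int
    r: float
    s_next: np.ndarray
    terminal: bool


class ReplayBuffer:
    """FIFO experience store with uniform without-replacement sampling."""

    def __init__(self, capacity: int = 10_000):
        if capacity < 1:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self._items: deque[Experience] = deque(maxlen=capacity)

    def add(self, exp: Experience) -> None:
        self._items.append(exp)

    def __len__(self) -> int:
        return len(self._items)

    def sample(self, batch_size: int, rng: np.random.Generator) -> list[Experience]:
        if batch_size > len(self):
            raise ValueError(
                f"buffer holds {len(self)} experiences, cannot sample {batch_size}")
        idx = rng.choice(len(self), size=batch_size, replace=False)
        items = list(self._items)
        return [items[i] for i in idx]


def replay_sample(buffer: ReplayBuffer, batch_size: int,
                  rng: np.random.Generator) -> list[Experience]:
    """Uniform without-replacement mini-batch from the buffer."""
    return buffer.sample(batch_size, rng)


def encode_observation(mask: np.ndarray, agent: int) -> np.ndarray:
    """Observation of agent `agent` (0-based): one-hot block then mask.

    The one-hot entry for the owning agent equals its mask bit, so an
    unselected agent's block is all zeros.
    """
    mask = np.asarray(mask).astype(np.uint8)
    n = mask.shape[0]
    if not (0 <= agent < n):
        raise ValueError(f"agent index {agent} outside [0, {n})")
    onehot = np.zeros(n, dtype=np.uint8)
    onehot[agent] = mask[agent]
    return np.concatenate([onehot, mask])


def allowed_flips(mask: np.ndarray, best_global: np.ndarray) -> np.ndarray:
    """0-based positions where mask and best_global differ (XOR).

    Identical masks would freeze every agent, so that degenerate case
    falls back to the full position set.
    """
    mask = np.asarray(mask).astype(np.uint8)
    best_global = np.asarray(best_global).astype(np.uint8)
    if mask.shape != best_global.shape:
        raise ValueError("mask length mismatch")
    diff = np.flatnonzero(mask ^ best_global)
    if diff.size == 0:
        return np.arange(mask.shape[0])
    return diff


def compute_reward(params: RewardParams, acc_prev: float, acc_curr: float,
                   k_prev: int, k_curr: int) -> float:
    """Three-branch reward on consecutive accuracies and subset sizes."""
    if not (0 <= acc_prev <= 1 and 0 <= acc_curr <= 1):
        raise ValueError("accuracies must lie in [0, 1]")
    if acc_prev < acc_curr:
        return float(acc_curr)
    if acc_prev > acc_curr:
        return float(params.penalty_coeff * (acc_curr - acc_prev))
    sign = 1.0 if k_prev > k_curr else -1.0
    return float(sign * acc_curr * params.design_factor)


def q_update(q_current: float, r: float, max_next_q: float, alpha: float,
             gamma: float) -> float:
    """Temporal-difference value update (terminal steps pass max_next_q=0)."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    return q_current + alpha * (r + gamma * max_next_q - q_current)


def dqn_train_step(network: QNetwork, target_network: QNetwork,
                   batch: list[Experience], gamma: float) -> float:
    """One replay step: targets r + gamma * max_a' Q_target(s') (r alone on
    terminal transitions); returns the squared-error loss."""
    if not batch:
        raise ValueError("batch must be non-empty")
    states = np.stack([e.s for e in batch]).astype(float)
    actions = np.array([e.a for e in batch], dtype=int)
    rewards = np.array([e.r for e in batch], dtype=float)
    next_states = np.stack([e.s_next for e in batch]).astype(float)
    terminal = np.array([e.terminal for e in batch], dtype=bool)
    next_q = target_network.q_values(next_states).max(axis=1)
    targets = rewards + gamma * np.where(terminal, 0.0, next_q)
    return network.train_step(states, actions, targets)


class _BaseLocalSearch:
    """Shared stepping logic; subclasses provide value estimates/updates.

    The value function, exploration schedule (and, in deep mode, the
    replay buffer) persist across calls, so every bee and every outer
    iteration learns from the accumulated experience.
    """

    def __init__(self, n_features: int, qlearn: QLearnParams,
                 reward: RewardParams, seed: int = 0):
        self.n = n_features
        self.qlearn = qlearn
        self.reward = reward
        self.rng = np.random.default_rng(seed)
        self.eps = qlearn.eps0
        self.step_count = 0

    # -- value interface -------------------------------------------------
    def _greedy_action(self, obs: np.ndarray) -> int:
        raise NotImplementedError

    def _learn(self, exp: Experience) -> None:
        raise NotImplementedError

    # -- environment stepping --------------------------------------------
    def run(self, start: np.ndarray, best_global: np.ndarray, objective,
            budget: int) -> tuple[np.ndarray, FitnessResult]:
        """Run `budget` agent steps from `start`; return best mask visited."""
        if budget < 1:
            raise ValueError("budget must be >= 1")
        mask = np.asarray(start).astype(np.uint8).copy()
        best_global = np.asarray(best_global).astype(np.uint8)
        if mask.sum() == 0:
            mask[self.rng.integers(self.n)] = 1
        fit = objective(mask)
        best_mask, best_fit = mask.copy(), fit
        acc_prev, k_prev = fit.accuracy, fit.n_selected
        cursor = 0
        # the XOR restriction funnels a bee launched away from the incumbent;
        # once the trajectory reaches (or starts at) the incumbent there is
        # nothing left to funnel toward, so the rest of the run is free
        restricted = not np.array_equal(mask, best_global)
        for step in range(budget):
            if restricted and np.array_equal(mask, best_global):
                restricted = False
            if restricted:
                allowed = allowed_flips(mask, best_global)
            else:
                allowed = np.arange(self.n)
            # round-robin in index order over the agents able to act
            pos = allowed[allowed >= cursor]
            u = int(pos[0]) if pos.size else int(allowed[0])
            cursor = (u + 1) % self.n
            obs = encode_observation(mask, u)
            if self.rng.random() < self.eps:
                action = int(self.rng.integers(2))
            else:
                action = self._greedy_action(obs)
            new_mask = mask
            if action == 1:
                candidate = mask.copy()
                candidate[u] ^= 1
                if candidate.sum() == 0:  # an empty subset cannot be scored
                    action = 0
                else:
                    new_mask = candidate
            new_fit = objective(new_mask)
            r = compute_reward(self.reward, acc_prev, new_fit.accuracy,
                               k_prev, new_fit.n_selected)
            exp = Experience(obs, action, r,
                             encode_observation(new_mask, u),
                             terminal=(step == budget - 1))
            self._learn(exp)
            self.step_count += 1
            self.eps = max(self.qlearn.eps_min, self.eps * self.qlearn.eps_decay)
            if better(new_fit, best_fit):
                best_mask, best_fit = new_mask.copy(), new_fit
            mask = new_mask
            acc_prev, k_prev = new_fit.accuracy, new_fit.n_selected
        return best_mask, best_fit


class TabularQLocalSearch(_BaseLocalSearch):
    """Lookup-table Q-learning local search (the plain Q-learning hybrid)."""

    def __init__(self, n_features: int, qlearn: QLearnParams,
                 reward: RewardParams, seed: int = 0):
        super().__init__(n_features, qlearn, reward, seed)
        self.table: dict[tuple[bytes, int], float] = {}

    def _q(self, obs: np.ndarray, action: int) -> float:
        return self.table.get((obs.tobytes(), action), 0.0)

    def _greedy_action(self, obs: np.ndarray) -> int:
        # optimistic tie-break: an untried flip (both values at the zero
        # initialization) is preferred over staying put
        q0, q1 = self._q(obs, 0), self._q(obs, 1)
        return 1 if q1 >= q0 else 0

    def _learn(self, exp: Experience) -> None:
        max_next = 0.0 if exp.terminal else max(self._q(exp.s_next, 0),
                                                self._q(exp.s_next, 1))
        key = (exp.s.tobytes(), exp.a)
        self.table[key] = q_update(self.table.get(key, 0.0), exp.r, max_next,
                                   self.qlearn.alpha, self.qlearn.gamma)

    def table_text(self) -> str:
        """Sorted plain-text dump of the Q-table for inspection."""
        lines = []
        for (sb, a), q in sorted(self.table.items()):
            bits = "".join(str(b) for b in np.frombuffer(sb, dtype=np.uint8))
            lines.append(f"{bits} a={a} q={q:+.6f}")
        return "\n".join(lines)


class DeepQLocalSearch(_BaseLocalSearch):
    """Deep-Q local search: shared network, replay buffer, target copies."""

    def __init__(self, n_features: int, qlearn: QLearnParams,
                 reward: RewardParams, seed: int = 0):
        super().__init__(n_features, qlearn, reward, seed)
        net_rng = np.random.default_rng(seed + 1)
        self.network = QNetwork(2 * n_features, hidden=qlearn.hid_num,
                                lr=qlearn.lr, rng=net_rng)
        self.target = self.network.clone()
        self.buffer = ReplayBuffer(qlearn.buffer_capacity)

    def _greedy_action(self, obs: np.ndarray) -> int:
        return int(self.network.q_values(obs)[0].argmax())

    def _learn(self, exp: Experience) -> None:
        self.buffer.add(exp)
        q = self.qlearn
        if len(self.buffer) >= max(q.warmup, q.batch_size) and \
                self.step_count % q.train_every == 0:
            batch = self.buffer.sample(q.batch_size, self.rng)
            dqn_train_step(self.network, self.target, batch, q.gamma)
        if self.step_count % q.target_copy_every == 0:
            self.target.copy_from(self.network)


class HillClimbLocalSearch:
    """Best-improvement single-bit-flip hill climbing (the heuristic local
    search of plain bee-swarm optimization)."""

    def __init__(self, n_features: int, seed: int = 0):
        self.n = n_features
        self.rng = np.random.default_rng(seed)

    def run(self, start: np.ndarray, best_global: np.ndarray, objective,
            budget: int) -> tuple[np.ndarray, FitnessResult]:
        mask = np.asarray(start).astype(np.uint8).copy()
        if mask.sum() == 0:
            mask[self.rng.integers(self.n)] = 1
        current_fit = objective(mask)
        spent = 0
        while spent < budget:
            best_neighbor, best_neighbor_fit = None, None
            order = self.rng.permutation(self.n)
            for j in order:
                if spent >= budget:
                    break
                neighbor = mask.copy()
                neighbor[j] ^= 1
                if neighbor.sum() == 0:
                    continue
                nf = objective(neighbor)
                spent += 1
                if best_neighbor_fit is None or better(nf, best_neighbor_fit):
                    best_neighbor, best_neighbor_fit = neighbor, nf
            if best_neighbor_fit is not None and better(best_neighbor_fit,
                                                        current_fit):
                mask, current_fit = best_neighbor, best_neighbor_fit
            else:
                break
        return mask, current_fit


def make_local_search(mode: str, n_features: int, qlearn: QLearnParams,
                      reward: RewardParams, seed: int = 0):
    """Factory for the three local-search modes."""
    if mode == "hill":
        return HillClimbLocalSearch(n_features, seed=seed)
    if mode == "tabular-q":
        return TabularQLocalSearch(n_features, qlearn, reward, seed=seed)
    if mode == "deep-q":
        return DeepQLocalSearch(n_features, qlearn, reward, seed=seed)
    raise ValueError(f"unknown local-search mode {mode!r}")


def run_rl_local_search(start: np.ndarray, best_global: np.ndarray, objective,
                        budget: int, qlearn: QLearnParams | None = None,
                        reward: RewardParams | None = None,
                        seed: int = 0) -> tuple[np.ndarray, FitnessResult]:
    """One-shot RL local search (fresh learner); returns best (mask, fitness)."""
    qlearn = qlearn or QLearnParams()
    reward = reward or RewardParams()
    cls = TabularQLocalSearch if qlearn.mode == "tabular" else DeepQLocalSearch
    searcher = cls(len(start), qlearn, reward, seed=seed)
    return searcher.run(start, best_global, objective, budget)
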