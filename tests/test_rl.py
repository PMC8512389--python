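"""RL local search: observations, rewards, value updates, trajectories."""

import numpy as np
import pytest

from baroque._nn import QNetwork
from baroque.core import bitstring_to_mask, mask_to_bitstring
from baroque.evaluation import FunctionObjective, better
from baroque.rl import (DeepQLocalSearch, Experience, QLearnParams,
                        ReplayBuffer, RewardParams, TabularQLocalSearch,
                        allowed_flips, compute_reward, dqn_train_step,
                        encode_observation, q_update, replay_sample,
                        run_rl_local_search)
from tests.conftest import TOY_TARGET, toy_match_fraction


class TestEncodeObservation:
    def test_selected_agent_worked_example(self):
        # mask (10110), 3rd agent (0-based index 2) -> (0010010110)
        obs = encode_observation(bitstring_to_mask("10110"), 2)
        assert mask_to_bitstring(obs) == "0010010110"

    def test_unselected_agent_block_all_zero(self):
        obs = encode_observation(bitstring_to_mask("10110"), 1)
        assert mask_to_bitstring(obs) == "0000010110"

    @pytest.mark.parametrize("n", [3, 5, 9])
    def test_length_2n(self, n):
        mask = np.ones(n, dtype=np.uint8)
        assert encode_observation(mask, 0).shape == (2 * n,)

    def test_out_of_range_agent_rejected(self):
        with pytest.raises(ValueError):
            encode_observation(bitstring_to_mask("10110"), 5)


class TestAllowedFlips:
    def test_worked_example_four_positions(self):
        flips = allowed_flips(bitstring_to_mask("10110"),
                              bitstring_to_mask("01101"))
        assert sorted(flips) == [0, 1, 3, 4]  # 1st, 2nd, 4th, 5th bits
        assert len(flips) == 4

    def test_identical_masks_fall_back_to_full_set(self):
        m = bitstring_to_mask("10110")
        assert sorted(allowed_flips(m, m)) == [0, 1, 2, 3, 4]

    def test_complementary_masks_allow_everything(self):
        m = bitstring_to_mask("10110")
        assert sorted(allowed_flips(m, 1 - m)) == [0, 1, 2, 3, 4]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            allowed_flips(np.zeros(3, dtype=np.uint8), np.zeros(4, dtype=np.uint8))


class TestComputeReward:
    P = RewardParams()  # penalty 0.5, design factor 0.1

    def test_accuracy_increase_pays_new_accuracy(self):
        assert compute_reward(self.P, 0.80, 0.90, 5, 5) == pytest.approx(0.90)

    def test_accuracy_decrease_penalized_by_half_the_drop(self):
        assert compute_reward(self.P, 0.90, 0.80, 5, 5) == pytest.approx(-0.05)

    def test_flat_accuracy_sign_follows_feature_count(self):
        assert compute_reward(self.P, 0.90, 0.90, 10, 8) == pytest.approx(0.09)
        assert compute_reward(self.P, 0.90, 0.90, 8, 10) == pytest.approx(-0.09)

    def test_sign_contract(self):
        assert compute_reward(self.P, 0.5, 0.6, 3, 3) > 0
        assert compute_reward(self.P, 0.6, 0.5, 3, 3) < 0
        assert compute_reward(self.P, 0.5, 0.5, 3, 3) < 0  # equal counts: negative


class TestQUpdate:
    def test_myopic_limit(self):
        assert q_update(0.7, 2.0, 5.0, alpha=1.0, gamma=0.0) == 2.0

    def test_small_alpha_barely_moves(self):
        assert q_update(1.0, 0.0, 0.0, alpha=1e-9, gamma=0.9) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # 0 + 0.5 * (1 + 0.9*2 - 0) = 1.4
        assert q_update(0.0, 1.0, 2.0, alpha=0.5, gamma=0.9) == pytest.approx(1.4)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            q_update(0.0, 0.0, 0.0, alpha=0.0, gamma=0.9)


def _experiences(n, n_features=4, seed=0, terminal=False):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        mask = (rng.random(n_features) < 0.5).astype(np.uint8)
        u = int(rng.integers(n_features))
        out.append(Experience(encode_observation(mask, u), int(rng.integers(2)),
                              float(rng.random()),
                              encode_observation(mask, u), terminal))
    return out


class TestReplayBuffer:
    def test_fifo_eviction(self):
        buf = ReplayBuffer(capacity=5)
        for e in _experiences(8):
            buf.add(e)
        assert len(buf) == 5

    def test_full_sample_is_permutation(self):
        buf = ReplayBuffer(10)
        exps = _experiences(10)
        for e in exps:
            buf.add(e)
        batch = replay_sample(buf, 10, np.random.default_rng(0))
        assert {id(e) for e in batch} == {id(e) for e in exps}

    def test_underfull_sampling_rejected(self):
        buf = ReplayBuffer(10)
        buf.add(_experiences(1)[0])
        with pytest.raises(ValueError):
            replay_sample(buf, 2, np.random.default_rng(0))

    def test_seeded_sampling_reproducible(self):
        buf = ReplayBuffer(20)
        for e in _experiences(20):
            buf.add(e)
        b1 = replay_sample(buf, 5, np.random.default_rng(3))
        b2 = replay_sample(buf, 5, np.random.default_rng(3))
        assert [id(e) for e in b1] == [id(e) for e in b2]

    def test_sampling_frequencies_near_uniform(self):
        """Over 10000 draws of size 1 from 10 items, each item's selection
        count stays within 3 binomial SDs of the uniform expectation."""
        buf = ReplayBuffer(10)
        exps = _experiences(10)
        for e in exps:
            buf.add(e)
        rng = np.random.default_rng(0)
        counts = {id(e): 0 for e in exps}
        n_draws = 10_000
        for _ in range(n_draws):
            counts[id(replay_sample(buf, 1, rng)[0])] += 1
        p = 1 / 10
        sd = np.sqrt(n_draws * p * (1 - p))
        assert all(abs(c - n_draws * p) <= 3 * sd for c in counts.values())


class TestDQNTrainStep:
    def _nets(self, n_features=4, seed=0):
        rng = np.random.default_rng(seed)
        net = QNetwork(2 * n_features, hidden=32, lr=1e-2, rng=rng)
        target = net.clone()
        return net, target

    def test_terminal_targets_equal_rewards(self):
        net, target = self._nets()
        batch = _experiences(8, terminal=True)
        states = np.stack([e.s for e in batch]).astype(float)
        actions = np.array([e.a for e in batch])
        before = net.q_values(states)[np.arange(8), actions]
        rewards = np.array([e.r for e in batch])
        loss = dqn_train_step(net, target, batch, gamma=0.9)
        assert loss == pytest.approx(float(np.mean((before - rewards) ** 2)))

    def test_repeated_batch_drives_loss_down_10x(self):
        net, target = self._nets(seed=1)
        batch = _experiences(16, seed=2, terminal=True)
        first = dqn_train_step(net, target, batch, gamma=0.9)
        last = first
        for _ in range(49):
            last = dqn_train_step(net, target, batch, gamma=0.9)
        assert last <= first / 10

    def test_target_copy_makes_outputs_agree(self):
        net, target = self._nets(seed=3)
        for _ in range(5):
            dqn_train_step(net, target, _experiences(8, seed=4), gamma=0.9)
        x = np.random.default_rng(5).random((6, 8))
        assert not np.allclose(net.q_values(x), target.q_values(x))
        target.copy_from(net)
        np.testing.assert_allclose(net.q_values(x), target.q_values(x))


class TestRunLocalSearch:
    def test_budget_one_full_exploration(self, toy_objective):
        start = np.array([1, 0, 0, 0, 0, 0, 0, 0], dtype=np.uint8)
        qlearn = QLearnParams(eps0=1.0, eps_min=1.0, eps_decay=1.0)
        mask, fit = run_rl_local_search(start, TOY_TARGET, toy_objective, 1,
                                        qlearn=qlearn, seed=0)
        # better of the start and its single sampled neighbor
        assert fit.accuracy >= toy_objective(start).accuracy

    def test_result_never_worse_than_start(self, toy_objective):
        start = np.array([0, 1, 1, 0, 1, 0, 0, 1], dtype=np.uint8)
        start_fit = toy_objective(start)
        _, fit = run_rl_local_search(start, TOY_TARGET, toy_objective, 50,
                                     seed=1)
        assert not better(start_fit, fit)

    def test_restriction_keeps_hamming_non_increasing(self):
        """While the XOR restriction is active, each accepted flip equalizes
        one differing bit, so distance to the incumbent never grows."""
        from baroque.core import hamming

        target = TOY_TARGET
        best_global = target.copy()
        distances = []

        class Spy(FunctionObjective):
            def __call__(self, mask):
                distances.append(hamming(mask, best_global))
                return super().__call__(mask)

        obj = Spy(toy_match_fraction, 8)
        start = 1 - target  # complementary: every position differs
        run_rl_local_search(start, best_global, obj, 24,
                            qlearn=QLearnParams(eps0=0.5, eps_min=0.05),
                            seed=2)
        # trajectory may revisit equal distances (no-ops) but never increase
        # until the degenerate fallback (distance 0) is reached
        active = []
        for d in distances:
            active.append(d)
            if d == 0:
                break
        assert all(b <= a for a, b in zip(active, active[1:]))

    @pytest.mark.parametrize("mode", ["tabular", "deep"])
    def test_reaches_toy_optimum_most_seeds(self, mode):
        wins = 0
        for seed in range(5):
            obj = FunctionObjective(toy_match_fraction, 8)
            start = (np.random.default_rng(seed).random(8) < 0.5).astype(np.uint8)
            if start.sum() == 0:
                start[0] = 1
            _, fit = run_rl_local_search(start, start, obj, 500,
                                         qlearn=QLearnParams(mode=mode),
                                         seed=seed)
            wins += fit.accuracy == 1.0
        assert wins >= 4

    def test_tabular_values_converge_under_repetition(self):
        """Where each observation identifies the acting agent (N=2: at most
        one agent is unselected per mask), rewards are a deterministic
        function of (state, action), so with alpha=1, gamma=0 the Q-values
        stop changing once every visited pair repeats."""
        target = np.array([1, 0], dtype=np.uint8)
        obj = FunctionObjective(
            lambda m: float((m == target).mean()), 2)
        searcher = TabularQLocalSearch(2, QLearnParams(mode="tabular",
                                                       alpha=1.0, gamma=0.0,
                                                       eps0=1.0, eps_min=1.0,
                                                       eps_decay=1.0),
                                       RewardParams(), seed=0)
        start = np.array([0, 1], dtype=np.uint8)
        searcher.run(start, start, obj, 200)
        snapshot = dict(searcher.table)
        searcher.run(start, start, obj, 200)
        assert snapshot  # table was actually populated
        assert all(abs(searcher.table[k] - v) < 1e-9
                   for k, v in snapshot.items() if k in searcher.table)
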