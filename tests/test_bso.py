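"""Outer bee-swarm search: region spawning, reference advancement, full runs."""

import numpy as np
import pytest

from baroque.bso import (BSOConfig, BSOState, advance_reference,
                         generate_search_region, hill_climb_local_search,
                         run_bso)
from baroque.core import hamming
from baroque.evaluation import FitnessResult, FunctionObjective, better
from tests.conftest import TOY_TARGET, toy_match_fraction


class TestGenerateSearchRegion:
    def test_interval_flip_strategy_n16_flip4(self):
        """First four masks flip (0,4,8,12), (1,5,9,13), (2,6,10,14),
        (3,7,11,15) of the reference."""
        ref = np.zeros(16, dtype=np.uint8)
        masks = generate_search_region(ref, BSOConfig(nb=10, flip=4, seed=0))
        expected = [(0, 4, 8, 12), (1, 5, 9, 13), (2, 6, 10, 14), (3, 7, 11, 15)]
        for mask, exp in zip(masks[:4], expected):
            assert tuple(np.flatnonzero(mask)) == exp

    def test_block_flip_strategy_n16_flip4(self):
        """Next four masks flip the contiguous blocks (0-3), (4-7),
        (8-11), (12-15)."""
        ref = np.zeros(16, dtype=np.uint8)
        masks = generate_search_region(ref, BSOConfig(nb=10, flip=4, seed=0))
        expected = [(0, 1, 2, 3), (4, 5, 6, 7), (8, 9, 10, 11), (12, 13, 14, 15)]
        for mask, exp in zip(masks[4:8], expected):
            assert tuple(np.flatnonzero(mask)) == exp

    def test_all_masks_differ_from_reference(self):
        rng = np.random.default_rng(5)
        ref = (rng.random(20) < 0.5).astype(np.uint8)
        masks = generate_search_region(ref, BSOConfig(nb=10, flip=5, seed=5))
        assert len(masks) == 10
        assert all(hamming(m, ref) >= 1 for m in masks)

    def test_first_strategy_distances(self):
        # first-strategy mask i flips ceil((N - i)/flip) positions
        ref = np.zeros(16, dtype=np.uint8)
        masks = generate_search_region(ref, BSOConfig(nb=10, flip=5, seed=0))
        for i in range(5):
            assert hamming(masks[i], ref) == -(-(16 - i) // 5)

    def test_no_duplicates_and_no_empty_masks(self):
        ref = np.ones(12, dtype=np.uint8)
        masks = generate_search_region(ref, BSOConfig(nb=10, flip=3, seed=2))
        keys = {m.tobytes() for m in masks}
        assert len(keys) == len(masks)
        assert all(m.sum() >= 1 for m in masks)

    def test_flip_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            generate_search_region(np.zeros(4, dtype=np.uint8),
                                   BSOConfig(nb=5, flip=5, seed=0))


class TestHillClimb:
    def test_zero_budget_returns_start(self, toy_objective):
        start = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=np.uint8)
        mask, fit = hill_climb_local_search(start, 0, toy_objective)
        np.testing.assert_array_equal(mask, start)

    def test_reaches_target_from_any_start(self):
        """On the bit-match landscape every climb reaches the global
        optimum (enumeration of all 256 masks shows no other local
        optimum under single-bit flips)."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            start = (rng.random(8) < 0.5).astype(np.uint8)
            if start.sum() == 0:
                start[0] = 1
            obj = FunctionObjective(toy_match_fraction, 8)
            mask, fit = hill_climb_local_search(start, 500, obj, seed=1)
            assert fit.accuracy == 1.0
            np.testing.assert_array_equal(mask, TOY_TARGET)

    def test_never_worse_than_start(self, toy_objective):
        start = np.array([0, 1, 0, 0, 1, 1, 0, 1], dtype=np.uint8)
        start_fit = toy_objective(start)
        mask, fit = hill_climb_local_search(start, 30, toy_objective)
        assert not better(start_fit, fit)


def _state(ref, best, fit, chances, dance, candidates=()):
    s = BSOState(ref_sol=ref, best_global_sol=best, best_global_fit=fit,
                 n_chances=chances)
    s.dance = dance
    s.candidates = list(candidates)
    s.push_tabu(ref)
    return s


class TestAdvanceReference:
    def _fit(self, acc, n=1):
        return FitnessResult(accuracy=acc, n_selected=n, evaluator_id="e")

    def test_improvement_updates_global_and_resets_chances(self):
        rng = np.random.default_rng(0)
        ref = np.array([1, 0, 0, 0], dtype=np.uint8)
        winner = np.array([1, 1, 0, 0], dtype=np.uint8)
        state = _state(ref, ref, self._fit(0.5, 1), 1,
                       dance=[(winner, self._fit(0.9, 2))])
        advance_reference(state, BSOConfig(max_chances=3), rng)
        np.testing.assert_array_equal(state.best_global_sol, winner)
        assert state.n_chances == 3

    def test_three_nonimproving_iterations_trigger_diversification(self):
        """Hand-trace of the chance counter: with max_chances=3 the third
        consecutive non-improving advance fires diversification."""
        rng = np.random.default_rng(1)
        n = 6
        best = np.array([1, 0, 0, 0, 0, 0], dtype=np.uint8)
        state = BSOState(ref_sol=best.copy(), best_global_sol=best.copy(),
                         best_global_fit=self._fit(0.9, 1), n_chances=3)
        state.push_tabu(best)
        config = BSOConfig(max_chances=3)
        far = np.array([0, 1, 1, 1, 1, 1], dtype=np.uint8)
        near = np.array([1, 1, 0, 0, 0, 0], dtype=np.uint8)
        chances_seen = []
        for i in range(3):
            loser = np.zeros(n, dtype=np.uint8)
            loser[i + 1] = 1
            state.dance = [(loser, self._fit(0.5, 1))]
            state.candidates = [near.copy(), far.copy()]
            advance_reference(state, config, rng)
            chances_seen.append(state.n_chances)
        # chances drained 2, 1, then diversification refilled to 3
        assert chances_seen == [2, 1, 3]
        np.testing.assert_array_equal(state.ref_sol, far)  # furthest fresh

    def test_diversified_reference_never_tabu(self):
        rng = np.random.default_rng(2)
        best = np.array([1, 0, 0, 0], dtype=np.uint8)
        tabu_mask = np.array([0, 1, 1, 1], dtype=np.uint8)
        fresh = np.array([1, 1, 1, 0], dtype=np.uint8)
        state = _state(best, best, self._fit(0.9, 1), 0,
                       dance=[(best.copy(), self._fit(0.1, 1))],
                       candidates=[tabu_mask, fresh])
        state.push_tabu(tabu_mask)
        advance_reference(state, BSOConfig(max_chances=3), rng)
        assert not np.array_equal(state.ref_sol, tabu_mask)


class TestRunBSO:
    @pytest.mark.parametrize("mode", ["hill", "tabular-q", "deep-q"])
    def test_finds_toy_optimum_most_seeds(self, mode):
        """Enumerating all 256 masks fixes the optimum; each local-search
        mode reaches it in >= 4/5 seeds."""
        wins = 0
        for seed in range(5):
            obj = FunctionObjective(toy_match_fraction, 8)
            rep = run_bso(obj, BSOConfig(nb=5, flip=3, max_iter=20,
                                         local_search=mode, local_budget=10,
                                         seed=seed))
            wins += rep.best_fitness == 1.0
        assert wins >= 4

    def test_best_global_trace_non_decreasing(self, toy_objective):
        rep = run_bso(toy_objective, BSOConfig(nb=4, flip=3, max_iter=10,
                                               local_search="hill",
                                               local_budget=8, seed=3))
        trace = [h.best_fitness for h in rep.history]
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_seeded_determinism(self):
        reps = []
        for _ in range(2):
            obj = FunctionObjective(toy_match_fraction, 8)
            reps.append(run_bso(obj, BSOConfig(nb=4, flip=3, max_iter=8,
                                               local_search="deep-q",
                                               local_budget=6, seed=11)))
        assert reps[0].best_mask == reps[1].best_mask
        assert ([ (h.iteration, h.n_evaluations, h.best_fitness)
                  for h in reps[0].history]
                == [(h.iteration, h.n_evaluations, h.best_fitness)
                    for h in reps[1].history])

    def test_reference_never_repeats_a_tabu_mask(self):
        """Tabu soundness: when the would-be reference is already tabu,
        the advance falls back to a fresh mask."""
        rng = np.random.default_rng(7)
        fit = FitnessResult(accuracy=0.5, n_selected=1, evaluator_id="e")
        ref = np.array([1, 0, 0, 0], dtype=np.uint8)
        repeat = np.array([0, 0, 1, 1], dtype=np.uint8)
        state = _state(ref, ref,
                       FitnessResult(accuracy=0.9, n_selected=1,
                                     evaluator_id="e"),
                       2, dance=[(repeat.copy(), fit)],
                       candidates=[np.array([1, 1, 1, 1], dtype=np.uint8)])
        state.push_tabu(repeat)
        advance_reference(state, BSOConfig(max_chances=3), rng)
        assert not np.array_equal(state.ref_sol, repeat)
        # every stored tabu entry is unique
        assert len(state.tabu) == len(set(state.tabu))
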