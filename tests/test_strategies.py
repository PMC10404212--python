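"""Incremental update strategies: threshold, class probabilities, insertion
decision, and the full probability-based and actual-class update steps."""

import numpy as np
import pytest

from incfrnn.frnn import frnn_predict, nearest_neighbours
from incfrnn.pool import increment_usage
from incfrnn.strategies import (
    Strategy,
    UpdateConfig,
    apply_actual_class_update,
    apply_probability_update,
    class_probabilities,
    decide_insertion,
    insertion_threshold,
    relative_difference,
)

from conftest import build_pool, random_pool


class TestRelativeDifference:
    @pytest.mark.parametrize(
        "a,b,expect",
        [
            (0.8, 0.8, 0.0),
            (1.0, 0.5, 0.5 / 0.75),
            (0.6, 0.0, 2.0),
            (0.0, 0.0, 0.0),
        ],
    )
    def test_examples(self, a, b, expect):
        assert relative_difference(a, b) == pytest.approx(expect)

    def test_unsorted_pair_errors(self):
        with pytest.raises(ValueError):
            relative_difference(0.3, 0.5)


class TestInsertionThreshold:
    def test_single_pair(self):
        # hand evaluation: 0.5 * (0.5 / 0.75)
        assert insertion_threshold([1.0, 0.5]) == pytest.approx(1.0 / 3.0)

    def test_all_equal_sims_give_zero(self):
        assert insertion_threshold([0.7, 0.7, 0.7]) == 0.0

    def test_two_pairs(self):
        # hand evaluation: 0.5 * (0.2/0.9 + 0.2/0.7)
        expect = 0.5 * (0.2 / 0.9 + 0.2 / 0.7)
        assert insertion_threshold([1.0, 0.8, 0.6]) == pytest.approx(expect)

    def test_short_list_errors(self):
        with pytest.raises(ValueError):
            insertion_threshold([0.9])


class TestClassProbabilities:
    def test_hand_evaluation_two_neighbours_one_class(self):
        # neighbours: both class a (counters 1, 1); pool mass a=2, b=2
        pool = build_pool([[0.1], [0.2], [0.8], [0.9]], ["a", "a", "b", "b"])
        nl = nearest_neighbours(pool, np.r_[0.15], k=2)
        probs = class_probabilities(pool, nl)
        assert probs["a"] == pytest.approx((2 / 2) / 2)
        assert probs["b"] == 0.0

    def test_symmetric_split_gives_equal_probabilities(self):
        pool = build_pool([[0.1], [0.9], [0.3], [0.7]], ["a", "b", "a", "b"])
        nl = nearest_neighbours(pool, np.r_[0.5], k=2)
        probs = class_probabilities(pool, nl)
        assert probs["a"] == pytest.approx(probs["b"])

    def test_single_class_pool_has_unique_maximum(self):
        pool = build_pool([[0.1], [0.2]], ["a", "a"])
        nl = nearest_neighbours(pool, np.r_[0.15], k=2)
        probs = class_probabilities(pool, nl)
        assert max(probs, key=probs.get) == "a"

    def test_uses_pre_increment_counters(self):
        pool = build_pool([[0.1], [0.9]], ["a", "b"])
        increment_usage(pool, [0, 0])  # counter of object 0 becomes 3
        nl = nearest_neighbours(pool, np.r_[0.1], k=2)
        probs = class_probabilities(pool, nl)
        # a: (3/4)/3, b: (1/4)/1
        assert probs["a"] == pytest.approx(0.25)
        assert probs["b"] == pytest.approx(0.25)


class TestDecideInsertion:
    def test_truth_table_has_exactly_the_two_paper_cells(self):
        # strict-inequality table: (D vs thr) x (predicted vs best)
        assert decide_insertion(0.8, 0.3, "a", "b") is True  # condition 1
        assert decide_insertion(0.1, 0.3, "a", "a") is True  # condition 2
        assert decide_insertion(0.8, 0.3, "a", "a") is False
        assert decide_insertion(0.1, 0.3, "a", "b") is False

    def test_equality_never_inserts(self):
        assert decide_insertion(0.3, 0.3, "a", "a") is False
        assert decide_insertion(0.3, 0.3, "a", "b") is False


class TestProbabilityUpdate:
    def _step(self, pool, y, cfg):
        scores = frnn_predict(pool, y, cfg.k)
        return apply_probability_update(pool, y, scores, cfg)

    def test_unlimited_window_grows_monotonically(self, rng):
        pool, _, _ = random_pool(rng, 10, 2)
        cfg = UpdateConfig(k=3, window_size=0, strategy=Strategy.PROBABILITY)
        sizes = []
        for _ in range(30):
            _, ctx = self._step(pool, rng.uniform(size=2), cfg)
            assert not ctx.deleted_ids
            sizes.append(len(pool))
        assert sizes == sorted(sizes)

    def test_window_cap_enforced_after_insertion(self, rng):
        pool, _, _ = random_pool(rng, 10, 2)
        cfg = UpdateConfig(k=3, window_size=10, strategy=Strategy.PROBABILITY)
        for _ in range(50):
            self._step(pool, rng.uniform(size=2), cfg)
            assert len(pool) == 10

    def test_deterministic_replay(self, rng):
        cfg = UpdateConfig(k=3, window_size=8, strategy=Strategy.PROBABILITY)
        frames = []
        for _ in range(2):
            r = np.random.default_rng(5)
            pool = build_pool(r.uniform(size=(6, 2)), ["a", "b", "a", "b", "a", "b"])
            for _ in range(40):
                self._step(pool, r.uniform(size=2), cfg)
            frames.append(pool.to_frame())
        assert frames[0].equals(frames[1])

    def test_cold_start_inserts_unconditionally(self):
        pool = build_pool([[0.5, 0.5]], ["a"])
        cfg = UpdateConfig(k=5, window_size=0)
        scores = frnn_predict(pool, np.r_[0.9, 0.9], k=5)
        _, ctx = apply_probability_update(pool, np.r_[0.9, 0.9], scores, cfg)
        assert ctx.inserted and ctx.cold_start
        assert len(pool) == 2

    def test_inserted_object_carries_predicted_label(self, rng):
        pool = build_pool([[0.0], [0.1], [0.9]], ["a", "a", "b"])
        cfg = UpdateConfig(k=2, window_size=0)
        inserted_before = len(pool)
        for _ in range(20):
            y = rng.uniform(size=1)
            scores = frnn_predict(pool, y, cfg.k)
            _, ctx = apply_probability_update(pool, y, scores, cfg)
            if ctx.inserted:
                assert pool.objects()[-1].class_label == ctx.predicted
        assert len(pool) >= inserted_before

    def test_counter_mass_conservation(self, rng):
        """Counter mass changes by +k (usage) + 1 (insertion) - deleted mass."""
        pool, _, _ = random_pool(rng, 12, 2)
        cfg = UpdateConfig(k=4, window_size=12, strategy=Strategy.PROBABILITY)
        for _ in range(30):
            before = int(pool.counters.sum())
            frame_before = pool.to_frame().set_index("insertion_index")
            y = rng.uniform(size=2)
            scores = frnn_predict(pool, y, cfg.k)
            _, ctx = apply_probability_update(pool, y, scores, cfg)
            deleted_mass = sum(
                # counters of evicted objects as they stood after this
                # step's own usage increments
                int(frame_before.loc[i, "frequency_counter"])
                + (1 if i in ctx.neighbour_ids else 0)
                if i in frame_before.index
                else 1  # the object inserted this step, then evicted
                for i in ctx.deleted_ids
            )
            after = int(pool.counters.sum())
            expect = before + cfg.k + (1 if ctx.inserted else 0) - deleted_mass
            assert after == expect

    def test_equal_counters_reduce_to_fifo_eviction(self):
        pool = build_pool([[0.0], [0.2], [0.4], [0.6]], ["a", "a", "b", "b"])
        from incfrnn.strategies import _window_evict

        deleted = _window_evict(pool, 2)
        assert deleted == [0, 1]

    def test_never_reads_actual_label(self):
        import inspect

        params = inspect.signature(apply_probability_update).parameters
        assert "actual" not in params and "label" not in params


class TestActualClassUpdate:
    def test_correct_prediction_leaves_size_unchanged(self):
        pool = build_pool([[0.1], [0.9]], ["a", "b"])
        cfg = UpdateConfig(k=1, window_size=0, strategy=Strategy.ACTUAL_CLASS)
        apply_actual_class_update(pool, np.r_[0.12], "a", "a", cfg)
        assert len(pool) == 2

    def test_misclassification_inserts_actual_label(self):
        pool = build_pool([[0.1], [0.9]], ["a", "b"])
        cfg = UpdateConfig(k=1, window_size=0, strategy=Strategy.ACTUAL_CLASS)
        apply_actual_class_update(pool, np.r_[0.12], "a", "b", cfg)
        assert len(pool) == 3
        assert pool.objects()[-1].class_label == "b"

    def test_cap_plus_misclassification_evicts_least_used(self):
        pool = build_pool([[0.1], [0.5], [0.9]], ["a", "a", "b"])
        increment_usage(pool, [0, 2])  # counters (2, 1, 2)
        cfg = UpdateConfig(k=1, window_size=3, strategy=Strategy.ACTUAL_CLASS)
        apply_actual_class_update(pool, np.r_[0.85], "b", "a", cfg)
        assert len(pool) == 3
        indices = [o.insertion_index for o in pool.objects()]
        assert 1 not in indices  # least-used original object evicted


def test_pool_size_bounded_through_any_stream(rng):
    pool, _, _ = random_pool(rng, 15, 2)
    cfg = UpdateConfig(k=3, window_size=10, strategy=Strategy.PROBABILITY)
    for _ in range(60):
        y = rng.uniform(size=2)
        scores = frnn_predict(pool, y, cfg.k)
        apply_probability_update(pool, y, scores, cfg)
        assert len(pool) <= max(15, cfg.window_size)
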