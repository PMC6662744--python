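"""Selection rules, transfer bookkeeping, determinism and stopping."""

import numpy as np
import pytest

from mircotrain import (
    CoTrainConfig,
    TwoViewSimConfig,
    ViewState,
    gen_two_view,
    plateau_stop,
    run_cotraining,
    run_passive,
    run_selftraining,
    select_top_confident,
)
from mircotrain.cotrain import TrainingTrace
from mircotrain.datatypes import NEGATIVE, POSITIVE


class TestSelectTopConfident:
    def test_basic(self):
        assert select_top_confident({"a": 0.9, "b": 0.2, "c": 0.6}) == ("a", "b")

    def test_lexicographic_tie_break(self):
        assert select_top_confident({"b": 0.9, "a": 0.9, "c": 0.1})[0] == "a"

    def test_no_half_threshold_gate(self):
        # argmax is the positive pick even when every score is below 0.5
        assert select_top_confident({"a": 0.4, "b": 0.3}) == ("a", "b")

    def test_distinct_even_when_scores_equal(self):
        pos, neg = select_top_confident({"a": 0.5, "b": 0.5})
        assert (pos, neg) == ("a", "b")

    def test_pool_exhausted(self):
        with pytest.raises(ValueError, match="exhausted"):
            select_top_confident({"a": 0.9})


class TestPlateauStop:
    def test_small_gains_stop(self):
        trace = {"v": [0.5, 0.8, 0.80, 0.801]}
        assert plateau_stop(trace, window=2, epsilon=0.01) is True

    def test_rising_curve_continues(self):
        trace = {"v": [0.5, 0.55, 0.60, 0.65]}
        assert plateau_stop(trace, window=2, epsilon=0.01) is False

    def test_requires_both_views_flat(self):
        trace = {"v1": [0.8, 0.8, 0.8], "v2": [0.5, 0.6, 0.7]}
        assert plateau_stop(trace, window=2, epsilon=0.01) is False

    def test_insufficient_history(self):
        with pytest.raises(ValueError, match="insufficient"):
            plateau_stop({"v": [0.5, 0.6]}, window=2, epsilon=0.01)


class TestCoTraining:
    def test_train_sizes_grow_by_two_per_iteration(self, small_two_view, fast_factory):
        for k in (0, 3, 5):
            va, vb = small_two_view["states"]()
            run_cotraining(
                va, vb, small_two_view["holdout"],
                CoTrainConfig(iterations=k, rng_seed=1), fast_factory,
            )
            assert len(va.train) == 10 + 2 * k
            assert len(vb.train) == 10 + 2 * k

    def test_conservation_and_cross_pool(self, small_two_view, fast_factory):
        va, vb = small_two_view["states"]()
        initial = set(va.train.instance_ids) | set(va.pool.instance_ids)
        _, trace = run_cotraining(
            va, vb, small_two_view["holdout"],
            CoTrainConfig(iterations=4, rng_seed=1), fast_factory,
        )
        transferred = {t.transferred_id for t in trace.transfers}
        for view in (va, vb):
            ids = set(view.train.instance_ids) | set(view.pool.instance_ids)
            assert ids | transferred == initial
            assert len(view.train.instance_ids) == len(set(view.train.instance_ids))
        # a donor's transfer never lands in its own train set (cross-view rule)
        for t in trace.transfers:
            donor = va if t.view == "seq" else vb
            assert t.transferred_id not in donor.train.instance_ids[10:]
        # transferred ids vanish from both pools
        for t in trace.transfers:
            assert t.transferred_id not in va.pool.instance_ids
            assert t.transferred_id not in vb.pool.instance_ids

    def test_deterministic_trace(self, small_two_view, fast_factory):
        runs = []
        for _ in range(2):
            va, vb = small_two_view["states"]()
            _, trace = run_cotraining(
                va, vb, small_two_view["holdout"],
                CoTrainConfig(iterations=3, rng_seed=42), fast_factory,
            )
            runs.append(trace)
        assert runs[0].transfers == runs[1].transfers
        assert runs[0].auprc == runs[1].auprc
        assert runs[0].to_frame().equals(runs[1].to_frame())

    def test_all_transfers_correct_on_separable_data(self, fast_factory):
        # wide separation: every confident pick should match hidden truth
        from mircotrain import SplitSpec, split_and_seed

        cfg = TwoViewSimConfig(
            n_pos=60, n_neg=60, dims_a=3, dims_b=3, sep_a=5.0, sep_b=5.0,
            noise_dims_a=1, noise_dims_b=1, rng_seed=9,
        )
        view_a, view_b, _ = gen_two_view(cfg)
        spec = SplitSpec(rng_seed=9)
        sa, pa, ha = split_and_seed(view_a, spec)
        sb, pb, hb = split_and_seed(view_b, spec)
        _, trace = run_cotraining(
            ViewState("seq", sa, pa), ViewState("expr", sb, pb), (ha, hb),
            CoTrainConfig(iterations=6, rng_seed=9), fast_factory,
        )
        assert all(t.correct for t in trace.transfers)

    def test_pool_exhaustion_truncates_with_flag(self, small_two_view, fast_factory):
        va, vb = small_two_view["states"]()
        # shrink the pools to 4 shared instances: 1 iteration drains them
        keep = va.pool.instance_ids[:4]
        va.pool = va.pool.subset(keep)
        vb.pool = vb.pool.subset(keep)
        _, trace = run_cotraining(
            va, vb, small_two_view["holdout"],
            CoTrainConfig(iterations=10, rng_seed=1), fast_factory,
        )
        assert trace.status == "pool_exhausted"
        assert len(va.train) < 10 + 2 * 10

    def test_plateau_rule_can_stop_early(self, small_two_view, fast_factory):
        va, vb = small_two_view["states"]()
        _, trace = run_cotraining(
            va, vb, small_two_view["holdout"],
            CoTrainConfig(iterations=10, rng_seed=1, stop_rule="plateau",
                          plateau_window=2, plateau_epsilon=1.0),
            fast_factory,
        )
        # epsilon=1 makes any curve a plateau at the first legal check
        assert trace.status == "plateau"
        assert len(trace.auprc["seq"]) < 11


class TestSelfTraining:
    def test_train_size_and_self_transfer(self, small_two_view, fast_factory):
        va, _ = small_two_view["states"]()
        _, trace = run_selftraining(
            va, small_two_view["holdout"][0],
            CoTrainConfig(iterations=4, rng_seed=1), fast_factory,
        )
        assert len(va.train) == 10 + 2 * 4
        for t in trace.transfers:  # picks land in the view's own train set
            assert t.transferred_id in va.train.instance_ids

    def test_first_selection_matches_cotraining(self, small_two_view, fast_factory):
        config = CoTrainConfig(iterations=1, rng_seed=5)
        va1, vb1 = small_two_view["states"]()
        _, co_trace = run_cotraining(
            va1, vb1, small_two_view["holdout"], config, fast_factory
        )
        va2, _ = small_two_view["states"]()
        _, self_trace = run_selftraining(
            va2, small_two_view["holdout"][0], config, fast_factory
        )
        co_first = [t.transferred_id for t in co_trace.transfers if t.view == "seq"]
        self_first = [t.transferred_id for t in self_trace.transfers]
        assert co_first == self_first  # same model, same scores, same picks


class TestPassive:
    def test_train_sizes(self, small_two_view, fast_factory):
        va, vb = small_two_view["states"]()
        run_passive(
            va, vb, small_two_view["holdout"],
            CoTrainConfig(iterations=4, rng_seed=1), fast_factory,
        )
        assert len(va.train) == 10 + 2 * 4 and len(vb.train) == 10 + 2 * 4

    def test_labels_follow_predicted_class(self, small_two_view, fast_factory):
        va, vb = small_two_view["states"]()
        _, trace = run_passive(
            va, vb, small_two_view["holdout"],
            CoTrainConfig(iterations=5, rng_seed=3), fast_factory,
        )
        for t in trace.transfers:
            if not t.fallback:
                # confidence stored as the predicted class's probability
                assert t.confidence > 0.5

    def test_fallback_when_stratum_empty(self, fast_factory):
        """All-positive pools force the negative pick onto the extreme score."""

        class AlwaysHigh:
            def fit(self, X, y):
                return self

            def score(self, X):
                return np.full(len(X), 0.9)

        from mircotrain import SplitSpec, split_and_seed

        cfg = TwoViewSimConfig(n_pos=30, n_neg=30, dims_a=2, dims_b=2,
                               noise_dims_a=0, noise_dims_b=0, rng_seed=4)
        view_a, view_b, _ = gen_two_view(cfg)
        spec = SplitSpec(rng_seed=4)
        sa, pa, ha = split_and_seed(view_a, spec)
        sb, pb, hb = split_and_seed(view_b, spec)
        _, trace = run_passive(
            ViewState("seq", sa, pa), ViewState("expr", sb, pb), (ha, hb),
            CoTrainConfig(iterations=1, rng_seed=4), lambda seed: AlwaysHigh(),
        )
        negatives = [t for t in trace.transfers if t.assigned_label == NEGATIVE]
        assert negatives and all(t.fallback for t in negatives)

    def test_can_incur_mislabels_unlike_cotraining(self, small_two_view, fast_factory):
        va, vb = small_two_view["states"]()
        _, trace = run_passive(
            va, vb, small_two_view["holdout"],
            CoTrainConfig(iterations=8, rng_seed=7), fast_factory,
        )
        assert all(t.correct is not None for t in trace.transfers)
        assert trace.n_incorrect() >= 0  # flags recorded; mislabels possible


class TestNoLearningEquivalence:
    def test_zero_iterations_same_scores_across_strategies(
        self, small_two_view, fast_factory
    ):
        config = CoTrainConfig(iterations=0, rng_seed=13)
        hold = small_two_view["holdout"]
        scores = {}
        va, vb = small_two_view["states"]()
        models, _ = run_cotraining(va, vb, hold, config, fast_factory)
        scores["cotrain"] = models["seq"].score(hold[0].values)
        va, vb = small_two_view["states"]()
        models, _ = run_passive(va, vb, hold, config, fast_factory)
        scores["passive"] = models["seq"].score(hold[0].values)
        va, _ = small_two_view["states"]()
        model, _ = run_selftraining(va, hold[0], config, fast_factory)
        scores["self"] = model.score(hold[0].values)
        np.testing.assert_array_equal(scores["cotrain"], scores["passive"])
        np.testing.assert_array_equal(scores["cotrain"], scores["self"])


def test_trace_frame_columns(small_two_view, fast_factory):
    va, vb = small_two_view["states"]()
    _, trace = run_cotraining(
        va, vb, small_two_view["holdout"],
        CoTrainConfig(iterations=2, rng_seed=1), fast_factory,
    )
    frame = trace.to_frame()
    assert {
        "iteration", "view", "transferred_id", "assigned_label",
        "confidence", "correct", "auprc_seq", "auprc_expr",
    } <= set(frame.columns)
    assert ((frame.confidence >= 0) & (frame.confidence <= 1)).all()
    assert len(frame) == 2 * 2 * 2  # 2 iterations x 2 views x 2 transfers
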