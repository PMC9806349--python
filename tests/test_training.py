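import numpy as np
import pytest

from pairfc.attention import AttentionParams, init_params
from pairfc.training import (
    LossConfig,
    SubjectPair,
    TrainConfig,
    contrastive_loss,
    forward_pair,
    sample_pairs,
    train,
    _pair_loss_and_grads,
)

from conftest import make_scan
from oracles import siamese_pair_bruteforce


class TestContrastiveLoss:
    @pytest.mark.parametrize(
        "s, y, margin, expected",
        [
            (1.2, 1, 1.0, 0.0),      # same-class similarity above margin
            (1.0, 1, 1.0, 0.0),
            (0.5, 0, 1.0, 0.25),
            (0.2, 1, 1.0, 0.64),
            (-0.3, 0, 0.5, 0.09),
        ],
    )
    def test_examples(self, s, y, margin, expected):
        assert contrastive_loss(s, y, LossConfig(margin=margin)) == pytest.approx(expected)

    def test_matches_direct_substitution_on_grid(self):
        for s in np.linspace(-2, 2, 21):
            for y in (0, 1):
                for margin in (0.3, 1.0, 1.7):
                    direct = (1 - y) * s**2 + y * max(margin - s, 0.0) ** 2
                    assert contrastive_loss(float(s), y, LossConfig(margin=margin)) == pytest.approx(direct)
                    assert contrastive_loss(float(s), y, LossConfig(margin=margin)) >= 0.0

    def test_zero_exactly_when_branch_satisfied(self):
        cfg = LossConfig(margin=0.8)
        assert contrastive_loss(0.9, 1, cfg) == 0.0
        assert contrastive_loss(0.0, 0, cfg) == 0.0
        assert contrastive_loss(0.7, 1, cfg) > 0.0
        assert contrastive_loss(0.1, 0, cfg) > 0.0

    def test_margin_must_be_positive(self):
        with pytest.raises(ValueError, match="margin"):
            LossConfig(margin=0.0)


class TestSamplePairs:
    def test_determinism_and_balance(self, toy_labeled_cohort):
        pairs_a = sample_pairs(toy_labeled_cohort, 100, balance=0.5, seed=9)
        pairs_b = sample_pairs(toy_labeled_cohort, 100, balance=0.5, seed=9)
        assert [(p.first.scan_id, p.second.scan_id) for p in pairs_a] == [
            (p.first.scan_id, p.second.scan_id) for p in pairs_b
        ]
        assert sum(p.y for p in pairs_a) == 50
        assert all(p.first is not p.second for p in pairs_a)

    def test_single_class_rejected(self, rng):
        cohort = [make_scan(rng, "NC", f"NC_{i}") for i in range(4)]
        with pytest.raises(ValueError, match="both classes"):
            sample_pairs(cohort, 10)

    def test_tiny_class_rejected(self, rng):
        cohort = [make_scan(rng, "NC", f"NC_{i}") for i in range(3)]
        cohort.append(make_scan(rng, "patient", "PT_0"))
        with pytest.raises(ValueError, match="fewer than 2"):
            sample_pairs(cohort, 10)


class TestForwardPair:
    def test_identical_scans_have_zero_loss_at_unit_margin(self, rng):
        a = make_scan(rng, "NC", "A")
        b = make_scan(rng, "NC", "B")
        b.fcm.series = a.fcm.series.copy()
        params = init_params(a.fcm.n_windows, seed=0)
        s, loss = forward_pair(SubjectPair(a, b), params, LossConfig(margin=1.0))
        assert s == pytest.approx(1.0)
        assert loss == pytest.approx(0.0)

    def test_swapping_branches_changes_nothing(self, rng):
        a = make_scan(rng, "NC", "A")
        b = make_scan(rng, "patient", "B")
        params = init_params(a.fcm.n_windows, seed=1)
        cfg = LossConfig(margin=0.6)
        assert forward_pair(SubjectPair(a, b), params, cfg) == pytest.approx(
            forward_pair(SubjectPair(b, a), params, cfg)
        )

    @pytest.mark.parametrize("aggregation", ["mean", "sum"])
    def test_matches_straightline_oracle(self, rng, aggregation):
        a = make_scan(rng, "NC", "A", n_rois=3, n_windows=4)
        b = make_scan(rng, "patient", "B", n_rois=3, n_windows=4)
        params = AttentionParams(
            rng.normal(size=(2, 4)), rng.normal(size=(2, 4)), rng.normal(size=(4, 4))
        )
        cfg = LossConfig(margin=0.7, aggregation=aggregation)
        pair = SubjectPair(a, b)
        s, loss = forward_pair(pair, params, cfg)
        s_ref, loss_ref = siamese_pair_bruteforce(
            a.fcm.series, b.fcm.series,
            params.w_query, params.w_key, params.w_value,
            pair.y, cfg.margin, aggregation,
        )
        assert s == pytest.approx(s_ref, abs=1e-10)
        assert loss == pytest.approx(loss_ref, abs=1e-10)

    def test_gradients_match_central_differences(self, rng):
        """Reverse-mode gradients of the full pair loss vs finite differences,
        sampled away from the hinge point."""
        cfg = LossConfig(margin=0.7)
        checked = 0
        attempts = 0
        while checked < 8 and attempts < 30:
            attempts += 1
            a = make_scan(rng, "NC", "A", n_rois=3, n_windows=4)
            b = make_scan(rng, "patient" if attempts % 2 else "NC", "B", n_rois=3, n_windows=4)
            pair = SubjectPair(a, b)
            params = AttentionParams(
                rng.normal(0, 0.5, (3, 4)), rng.normal(0, 0.5, (3, 4)), rng.normal(0, 0.5, (4, 4))
            )
            s, _, grads = _pair_loss_and_grads(pair, params, cfg)
            if abs(cfg.margin - s) < 1e-3:
                continue
            h = 1e-6
            for name in ("w_query", "w_key", "w_value"):
                w = getattr(params, name)
                i, j = rng.integers(w.shape[0]), rng.integers(w.shape[1])
                up, down = params.copy(), params.copy()
                getattr(up, name)[i, j] += h
                getattr(down, name)[i, j] -= h
                fd = (forward_pair(pair, up, cfg)[1] - forward_pair(pair, down, cfg)[1]) / (2 * h)
                assert grads[name][i, j] == pytest.approx(fd, rel=1e-4, abs=1e-9)
            checked += 1
        assert checked >= 8


class TestTrain:
    def test_zero_learning_rate_is_a_no_op(self, toy_labeled_cohort):
        params = init_params(toy_labeled_cohort[0].fcm.n_windows, seed=0)
        state = train(
            toy_labeled_cohort,
            params,
            LossConfig(),
            TrainConfig(learning_rate=0.0, epochs=3, pairs_per_epoch=16, seed=1),
        )
        for (_, w0), (_, w1) in zip(params.items(), state.params.items()):
            np.testing.assert_array_equal(w0, w1)
        assert len(state.loss_history) == 3

    def test_same_seed_reproduces_loss_history_bitwise(self, small_strong_cohort):
        cohort, _ = small_strong_cohort
        params = init_params(cohort[0].fcm.n_windows, seed=2)
        cfg = TrainConfig(epochs=4, pairs_per_epoch=32, seed=7)
        h1 = train(cohort, params, LossConfig(), cfg).loss_history
        h2 = train(cohort, params, LossConfig(), cfg).loss_history
        assert h1 == h2

    def test_loss_decreases_on_strong_effect_cohort(self, small_strong_cohort):
        cohort, _ = small_strong_cohort
        params = init_params(cohort[0].fcm.n_windows, seed=3)
        state = train(
            cohort, params, LossConfig(), TrainConfig(epochs=12, pairs_per_epoch=64, seed=11)
        )
        assert state.loss_history[-1] < state.loss_history[0]
        assert all(np.isfinite(state.loss_history))

    def test_validation_selection_returns_best_epoch_params(self, small_strong_cohort):
        cohort, _ = small_strong_cohort
        params = init_params(cohort[0].fcm.n_windows, seed=4)
        half = len(cohort) // 2
        state = train(
            cohort[:half] + cohort[-half // 2:],
            params,
            LossConfig(),
            TrainConfig(epochs=3, pairs_per_epoch=16, seed=5),
            val_cohort=cohort,
        )
        assert state.best_epoch is not None
        assert len(state.val_history) == 3

    def test_single_class_cohort_rejected(self, rng):
        cohort = [make_scan(rng, "NC", f"NC_{i}") for i in range(4)]
        params = init_params(cohort[0].fcm.n_windows, seed=0)
        with pytest.raises(ValueError, match="2 classes|both classes|>=2 scans"):
            train(cohort, params)
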