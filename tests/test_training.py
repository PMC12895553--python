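import numpy as np
import pytest

from twinbrain import synthetic_cohort as sc
from twinbrain import training
from twinbrain import twin_model as tm
from twinbrain.task_codec import EF_TASK, MultimodalSequence
from twinbrain.training import LossConfig, TrainConfig


def _seq(n_steps, n_regions=4, seed=0):
    rng = np.random.default_rng(seed)
    return MultimodalSequence(
        sensory=rng.random((n_steps, 8)),
        condition=np.zeros((n_steps, 1)),
        action=(rng.random((n_steps, 3)) < 0.01).astype(float),
        bold=rng.normal(size=(n_steps, n_regions)),
        step_s=0.08,
    )


class TestSegmentSequences:
    def test_2460_steps_gives_9_segments(self):
        segs = training.segment_sequences(_seq(2460), 262)
        assert len(segs) == 9
        assert all(s.n_steps == 262 for s in segs)
        # 9 * 262 = 2358 -> 102 trailing steps dropped
        assert 2460 - 9 * 262 == 102

    def test_exact_length_gives_one_segment(self):
        assert len(training.segment_sequences(_seq(262), 262)) == 1

    def test_segment_len_one_gives_t_segments(self):
        assert len(training.segment_sequences(_seq(7), 1)) == 7

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            training.segment_sequences(_seq(10), 50)

    def test_segments_carry_time_offsets(self):
        segs = training.segment_sequences(_seq(524), 262)
        assert segs[1].t0_s == pytest.approx(262 * 0.08)


class FakePred:
    def __init__(self, prob, bold):
        self.action_prob = prob
        self.bold_pred = bold
        p = np.clip(prob, 1e-12, 1 - 1e-12)
        self.action_logit = np.log(p / (1 - p))


class TestCombinedLoss:
    def test_perfect_prediction_saturates_to_zero(self):
        a = np.array([[1.0, 0.0]])
        pred = FakePred(np.array([[1 - 1e-9, 1e-9]]), np.array([[2.0]]))
        L, La, Lb = training.combined_loss(pred, a, np.array([[2.0]]), LossConfig())
        assert L == pytest.approx(0.0, abs=1e-6)

    def test_single_element_half_probability(self):
        pred = FakePred(np.array([[0.5]]), np.zeros((1, 0)))
        L, La, Lb = training.combined_loss(pred, np.array([[1.0]]),
                                           np.zeros((1, 0)), LossConfig())
        assert La == pytest.approx(np.log(2.0), abs=1e-9)
        assert La == pytest.approx(0.6931, abs=1e-4)
        assert Lb == 0.0

    def test_unit_bold_error(self):
        pred = FakePred(np.full((2, 1), 0.5), np.ones((2, 3)))
        L, La, Lb = training.combined_loss(
            pred, np.zeros((2, 1)), np.zeros((2, 3)), LossConfig(lambda_bold=2.0)
        )
        assert Lb == pytest.approx(2.0)

    def test_non_binary_targets_rejected(self):
        pred = FakePred(np.array([[0.5]]), np.zeros((1, 0)))
        with pytest.raises(ValueError, match="0, 1"):
            training.combined_loss(pred, np.array([[0.3]]), np.zeros((1, 0)),
                                   LossConfig())

    def test_loss_weights_validated(self):
        with pytest.raises(ValueError):
            LossConfig(lambda_action=0.0, lambda_bold=0.0)
        with pytest.raises(ValueError):
            LossConfig(lambda_action=-1.0)


class TestLossGradients:
    def test_lambda_action_zero_leaves_only_bold_gradient(self, rng):
        Y = rng.normal(size=(2, 6, 5))
        actions = (rng.random((2, 6, 2)) < 0.2).astype(float)
        bolds = rng.normal(size=(2, 6, 3))
        _, dY_bold_only = training._loss_and_grad_Y(
            Y, actions, bolds, LossConfig(lambda_action=0.0, lambda_bold=1.0), 2
        )
        _, dY_full = training._loss_and_grad_Y(
            Y, actions, bolds, LossConfig(lambda_action=1.0, lambda_bold=1.0), 2
        )
        np.testing.assert_array_equal(dY_bold_only[..., :2], 0.0)
        np.testing.assert_array_equal(dY_bold_only[..., 2:], dY_full[..., 2:])


def _tiny_splits(n_participants=5, seed=11):
    cfg = sc.CohortConfig(n_participants=n_participants, tasks=[EF_TASK],
                          ef_duration_s=98.0)
    cohort = sc.generate_cohort(cfg, seed)
    return training.prepare_splits(cohort, [EF_TASK], 100, 0.2)


def _tiny_model(splits):
    return tm.ModelConfig(n_in=splits[0].rsfcm.size, n_hidden_hyper=16,
                          n_hidden_main=16, n_bold=20, dropout=0.0)


class TestTrain:
    def test_lr_zero_leaves_parameters_unchanged(self):
        splits, _ = _tiny_splits()
        mc = _tiny_model(splits)
        init = tm.init_hypernet(mc, 0)
        hp, _ = training.train(
            splits, mc,
            train_cfg=TrainConfig(segment_len=100, lr=0.0, max_epochs=3,
                                  early_stop_patience=10, restore_best=False),
            init=init,
        )
        for name in hp.names():
            np.testing.assert_array_equal(getattr(hp, name), getattr(init, name))

    def test_same_seed_identical_logs_and_params(self):
        splits, _ = _tiny_splits()
        mc = _tiny_model(splits)
        cfg = TrainConfig(segment_len=100, lr=1e-3, max_epochs=4,
                          early_stop_patience=10, seed=5)
        hp1, log1 = training.train(splits, mc, train_cfg=cfg)
        hp2, log2 = training.train(splits, mc, train_cfg=cfg)
        assert log1.train_total == log2.train_total
        assert log1.val_total == log2.val_total
        for name in hp1.names():
            np.testing.assert_array_equal(getattr(hp1, name), getattr(hp2, name))

    def test_descent_on_tiny_cohort(self):
        splits, _ = _tiny_splits()
        mc = _tiny_model(splits)
        _, log = training.train(
            splits, mc,
            train_cfg=TrainConfig(segment_len=100, lr=1e-3, max_epochs=8,
                                  early_stop_patience=100, restore_best=False),
        )
        assert log.train_total[-1] < log.train_total[0]

    def test_200_epochs_halves_the_loss(self):
        """5 participants, 20 regions, 16/16 hidden: training loss drops by
        ≥ 50% within 200 epochs (threshold from pilot runs)."""
        splits, _ = _tiny_splits()
        mc = _tiny_model(splits)
        _, log = training.train(
            splits, mc, LossConfig(),
            TrainConfig(segment_len=100, lr=3e-3, max_epochs=200,
                        early_stop_patience=200, restore_best=False),
        )
        assert log.train_total[-1] < 0.5 * log.train_total[0]

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError, match="participant"):
            training.train([], tm.ModelConfig(n_in=4))

    def test_failing_probe_aborts_run(self):
        splits, _ = _tiny_splits()
        mc = _tiny_model(splits)
        cfg = TrainConfig(segment_len=100, lr=1e-3, max_epochs=10,
                          early_stop_patience=100, restore_best=False)
        _, log = training.train(splits, mc, train_cfg=cfg, probe_epoch=3,
                                probe=lambda hp: False)
        assert len(log.epochs) == 3
        assert log.stop_epoch == 2

    def test_resumed_optimizer_continues_without_reset(self):
        """Chunked training with a persistent Adam matches one long run."""
        splits, _ = _tiny_splits()
        mc = _tiny_model(splits)
        init = tm.init_hypernet(mc, 4)

        cfg_long = TrainConfig(segment_len=100, lr=1e-3, max_epochs=6, seed=2,
                               early_stop_patience=100, restore_best=False)
        hp_long, _ = training.train(splits, mc, train_cfg=cfg_long, init=init)

        opt = training.Adam(init.as_dict(), 1e-3)
        hp = init
        for _ in range(2):
            cfg = TrainConfig(segment_len=100, lr=1e-3, max_epochs=3, seed=2,
                              early_stop_patience=100, restore_best=False)
            hp, _ = training.train(splits, mc, train_cfg=cfg, init=hp, opt=opt)
        # same epoch count and shared Adam moments: end states agree closely
        # (not exactly: the chunked run re-seeds its batch permutation)
        for name in hp.names():
            np.testing.assert_allclose(getattr(hp, name), getattr(hp_long, name),
                                       atol=1e-3)


class TestBatchedEngineMatchesReference:
    def test_forward_agrees_with_single_sequence_rollout(self, rng):
        cfg = tm.ModelConfig(n_in=10, n_hidden_hyper=4, n_hidden_main=5,
                             n_sensor_plus_cond=9, n_action=3, n_bold=2,
                             dropout=0.0)
        hp = tm.init_hypernet(cfg, 2)
        X = rng.normal(size=(3, cfg.n_in))
        theta = tm.hypernet_forward(X, hp, cfg)
        views = training._theta_views(np.asarray(theta), cfg)
        inputs = rng.normal(size=(5, 12, cfg.n_sensor_plus_cond))
        pmap = np.array([0, 0, 1, 2, 2])
        hidden, Y = training._batched_rollout(views, pmap, inputs)
        for b in range(5):
            params = tm.MainNetParams(np.asarray(theta[pmap[b]]), cfg)
            ref = tm.rnn_rollout(params, inputs[b])
            np.testing.assert_allclose(hidden[b], ref.hidden, atol=1e-12)
            np.testing.assert_allclose(
                Y[b], np.concatenate([ref.action_logit, ref.bold_pred], axis=1),
                atol=1e-12,
            )

    def test_backward_matches_reference_backward(self, rng):
        cfg = tm.ModelConfig(n_in=10, n_hidden_hyper=4, n_hidden_main=5,
                             n_sensor_plus_cond=9, n_action=3, n_bold=2,
                             dropout=0.0)
        hp = tm.init_hypernet(cfg, 2)
        X = rng.normal(size=(2, cfg.n_in))
        theta = np.asarray(tm.hypernet_forward(X, hp, cfg))
        views = training._theta_views(theta, cfg)
        inputs = rng.normal(size=(2, 8, cfg.n_sensor_plus_cond))
        pmap = np.array([0, 1])
        hidden, Y = training._batched_rollout(views, pmap, inputs)
        dY = rng.normal(size=Y.shape)
        dtheta = training._batched_backward(views, pmap, inputs, hidden, dY, 2, cfg)
        for b in range(2):
            params = tm.MainNetParams(theta[b], cfg)
            ref, cache = tm.rnn_rollout(params, inputs[b], return_cache=True)
            dpacked, _ = tm.rollout_backward(dY[b], cache, params)
            np.testing.assert_allclose(dtheta[b], dpacked, atol=1e-10)


class TestEvaluate:
    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            training.evaluate(None, None, [])

    def test_metrics_reproducible(self):
        splits, _ = _tiny_splits()
        mc = _tiny_model(splits)
        hp = tm.init_hypernet(mc, 0)
        t1, s1 = training.evaluate(hp, mc, splits)
        t2, s2 = training.evaluate(hp, mc, splits)
        assert s1 == s2
        assert t1.equals(t2)
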