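"""Canned toy-scale configurations for tests and the acceptance report.

The toy cohort (40 participants, 20 regions, 32/32 hidden units) is the
desk-scale stand-in for the full-scale setup; it trains end to end on one CPU
in a few minutes.

Optimizing button-press timing from a near-silent action channel is bistable
at this scale: depending on the initialization, runs either sharpen presses
to confident probabilities or settle into a timid base-rate equilibrium.
:func:`train_toy_twin` therefore uses a deterministic multi-start scheme —
short trial runs scored by concordance on the *training* half only (the test
half is never consulted), continuing the first start that escapes. Everything
is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

from . import synthetic_cohort as sc
from . import task_codec
from . import training
from . import twin_model as tm
from .task_codec import EF_TASK
from .twin_model import generate_main_params, predicted_series, rnn_rollout


def toy_cohort_config(n_participants: int = 40, tasks: list[str] | None = None) -> sc.CohortConfig:
    return sc.CohortConfig(
        n_participants=n_participants,
        n_regions=20,
        tasks=tasks or [EF_TASK],
        ef_duration_s=197.6,
        stroop_duration_s=197.6,
        press_steps=3,  # 240-ms presses give the BCE enough positive mass
    )


def toy_model_config(n_in: int) -> tm.ModelConfig:
    return tm.ModelConfig(
        n_in=n_in, n_hidden_hyper=32, n_hidden_main=32, n_bold=20, dropout=0.0
    )


def toy_train_config(seed: int, max_epochs: int = 800) -> training.TrainConfig:
    # toy-scale optimization; the full-scale defaults live on TrainConfig itself
    return training.TrainConfig(
        segment_len=262,
        batch_size=50,
        lr=3e-3,
        max_epochs=max_epochs,
        early_stop_patience=max_epochs,
        val_fraction=0.1,
        seed=seed,
        restore_best=False,
    )


def toy_loss_config() -> training.LossConfig:
    return training.LossConfig(lambda_action=10.0, lambda_bold=1.0)


def train_half_concordance(
    hp: tm.HypernetParams,
    model_cfg: tm.ModelConfig,
    splits: list[training.ParticipantSplit],
    task: str = EF_TASK,
    threshold: float = 0.5,
) -> float:
    """Mean choice concordance over the training halves (no test-half peeking)."""
    values = []
    for s in splits:
        segs = sorted(s.train_segments + s.val_segments, key=lambda g: g.t0_s)
        seq = task_codec.MultimodalSequence(
            sensory=np.concatenate([g.sensory for g in segs]),
            condition=np.concatenate([g.condition for g in segs]),
            action=np.concatenate([g.action for g in segs]),
            bold=np.concatenate([g.bold for g in segs]),
            step_s=segs[0].step_s,
        )
        covered_s = seq.n_steps * seq.step_s
        events = s.train_events[task]
        events = events[events["onset"] < covered_s]
        if events.empty:
            continue
        params = generate_main_params(s.rsfcm, hp, model_cfg)
        pred_action, _ = predicted_series(rnn_rollout(params, seq.inputs()))
        obs = task_codec.decode_choices(seq.action, events, task, threshold, seq.step_s)
        pred = task_codec.decode_choices(pred_action, events, task, threshold, seq.step_s)
        values.append(task_codec.concordance_rate(pred, obs))
    return float(np.mean(values)) if values else 0.0


#: (seed offset, learning rate) per trial start. Escaping the timid
#: equilibrium depends jointly on the initialization and the step size, and
#: neither 3e-3 nor 5e-3 works for every cohort, so the starts alternate.
TRIAL_STARTS = ((0, 3e-3), (1000, 5e-3), (2000, 5e-3), (3000, 3e-3))


def train_toy_twin(
    seed: int = 7,
    chunk_epochs: int = 100,
    total_chunks: int = 12,
    stuck_check_chunk: int = 6,
    escape_concordance: float = 0.05,
    anneal_concordance: float = 0.3,
    good_enough: float = 0.5,
):
    """Generate the toy cohort and train the twin on the Emotional Faces task.

    Press-timing optimization at this scale is bistable and non-monotone:
    runs escape the timid base-rate equilibrium at unpredictable times and can
    later collapse out of the sharp solution again. The recipe therefore runs
    up to ``len(TRIAL_STARTS)`` starts, each trained in 100-epoch chunks with
    a persistent Adam state, scoring every chunk by choice concordance on the
    *training* half (the held-out test half is never consulted) and keeping
    the best-scoring snapshot. Once a start's concordance clears
    ``anneal_concordance`` the learning rate anneals to 1e-3 to consolidate;
    starts still below ``escape_concordance`` at the stuck check are
    abandoned. The best snapshot across starts is returned. Deterministic
    given ``seed``.

    Returns (cohort, splits, hypernet params, model config, training log).
    """
    cohort = sc.generate_cohort(toy_cohort_config(), seed)
    splits, _ = training.prepare_splits(cohort, [EF_TASK], 262, 0.1)
    model_cfg = toy_model_config(splits[0].rsfcm.size)
    loss_cfg = toy_loss_config()

    overall_best = None  # (concordance, hp, log)
    for offset, start_lr in TRIAL_STARTS:
        start_seed = seed + offset
        # action biases start at the press base-rate logit, not probability 0.5
        hp = tm.init_hypernet(model_cfg, np.random.default_rng(start_seed),
                              action_bias_logit=-4.8)
        opt = training.Adam(hp.as_dict(), start_lr)
        lr = start_lr
        start_best = None
        last_log = None
        for chunk in range(total_chunks):
            cfg = toy_train_config(start_seed + 17 * chunk + 1, chunk_epochs)
            cfg.lr = lr
            hp, last_log = training.train(
                splits, model_cfg, loss_cfg, cfg, init=hp, opt=opt
            )
            conc = train_half_concordance(hp, model_cfg, splits)
            if start_best is None or conc > start_best[0]:
                start_best = (conc, hp.copy(), last_log)
            if conc >= anneal_concordance:
                lr = 1e-3
            if chunk + 1 == stuck_check_chunk and start_best[0] < escape_concordance:
                break
        if overall_best is None or start_best[0] > overall_best[0]:
            overall_best = start_best
        if overall_best[0] >= good_enough:
            break

    _, hp, log = overall_best
    return cohort, splits, hp, model_cfg, log
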