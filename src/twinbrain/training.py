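"""End-to-end optimization of the hypernetwork through the main network.

The composite loss is binary cross-entropy on the action channels plus mean
squared error on the BOLD channels (each weighted, then summed). Training
sequences are segmented into fixed-length windows as a data-augmentation
strategy; the hidden state resets at every segment boundary. Gradients flow
through time in the main network and back into the hypernetwork; all of it is
hand-written numpy (no autograd framework is available here), vectorized over
(participant, segment) batches.

Full-scale defaults follow the source setup (segment 262 steps, batch 50,
Adam at lr 1e-6, ≤ 800 epochs with early stopping); toy-scale configs raise
the learning rate (see the package README).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import task_codec
from .preprocess import (
    NormalizationStats,
    RegionTimeSeries,
    fit_normalization,
    shift_events,
    temporal_split,
)
from .synthetic_cohort import GroundTruthCohort
from .task_codec import MultimodalSequence
from .twin_model import (
    HypernetParams,
    ModelConfig,
    count_main_params,
    generate_main_params,
    hypernet_backward,
    hypernet_forward,
    init_hypernet,
    param_slices,
    predicted_series,
    rnn_rollout,
    sigmoid,
    softplus,
)


@dataclass
class LossConfig:
    lambda_action: float = 1.0
    lambda_bold: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_action < 0 or self.lambda_bold < 0:
            raise ValueError("loss weights must be ≥ 0")
        if self.lambda_action == 0 and self.lambda_bold == 0:
            raise ValueError("at least one loss weight must be > 0")


@dataclass
class TrainConfig:
    segment_len: int = 262  # 20.96 s at 0.08 s steps
    batch_size: int = 50
    lr: float = 1e-6  # full-scale default; raise for scaled-down synthetic configs
    max_epochs: int = 800
    early_stop_patience: int = 50
    val_fraction: float = 0.1
    seed: int = 0
    restore_best: bool = True  # return the best-validation params, not the last

    def __post_init__(self) -> None:
        if self.segment_len < 1:
            raise ValueError("segment_len must be ≥ 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class TrainingLog:
    epochs: list[int] = field(default_factory=list)
    train_total: list[float] = field(default_factory=list)
    train_action: list[float] = field(default_factory=list)
    train_bold: list[float] = field(default_factory=list)
    val_total: list[float] = field(default_factory=list)
    val_action: list[float] = field(default_factory=list)
    val_bold: list[float] = field(default_factory=list)
    stop_epoch: int = -1
    wall_time_s: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "train_total": self.train_total,
                "train_action": self.train_action,
                "train_bold": self.train_bold,
                "val_total": self.val_total,
                "val_action": self.val_action,
                "val_bold": self.val_bold,
            }
        )


def segment_sequences(seq: MultimodalSequence, segment_len: int) -> list[MultimodalSequence]:
    """Contiguous non-overlapping segments; the trailing remainder is dropped."""
    if segment_len < 1:
        raise ValueError("segment_len must be ≥ 1")
    if seq.n_steps < segment_len:
        raise ValueError(
            f"sequence has {seq.n_steps} steps, shorter than segment_len={segment_len}"
        )
    out = []
    for k in range(seq.n_steps // segment_len):
        a, b = k * segment_len, (k + 1) * segment_len
        out.append(
            MultimodalSequence(
                sensory=seq.sensory[a:b],
                condition=seq.condition[a:b],
                action=seq.action[a:b],
                bold=seq.bold[a:b],
                step_s=seq.step_s,
                t0_s=seq.t0_s + a * seq.step_s,
            )
        )
    return out


def combined_loss(
    pred, target_action: np.ndarray, target_bold: np.ndarray, cfg: LossConfig
) -> tuple[float, float, float]:
    """(L, L_action, L_bold): weighted BCE + MSE, each a mean over all elements."""
    p = np.asarray(pred.action_prob, dtype=float)
    a = np.asarray(target_action, dtype=float)
    b = np.asarray(target_bold, dtype=float)
    if p.shape != a.shape:
        raise ValueError(f"action shapes differ: {p.shape} vs {a.shape}")
    if pred.bold_pred.shape != b.shape:
        raise ValueError(f"BOLD shapes differ: {pred.bold_pred.shape} vs {b.shape}")
    if not np.isin(a, (0.0, 1.0)).all():
        raise ValueError("target actions must be in {0, 1}")
    # stable logit-form BCE: softplus(z) - t*z == -[t log p + (1-t) log(1-p)]
    z = pred.action_logit
    l_action = cfg.lambda_action * float(np.mean(softplus(z) - a * z))
    l_bold = cfg.lambda_bold * float(np.mean((pred.bold_pred - b) ** 2)) if b.size else 0.0
    return l_action + l_bold, l_action, l_bold


# -- cohort preparation -------------------------------------------------------


@dataclass
class ParticipantSplit:
    """Per-participant training inputs and held-out test material for one cohort."""

    rsfcm: np.ndarray  # Fisher-z edge vector
    train_segments: list[MultimodalSequence]  # across tasks
    val_segments: list[MultimodalSequence]
    test: dict[str, MultimodalSequence]  # per task, normalized BOLD
    test_events: dict[str, pd.DataFrame]  # rebased to the test window
    train_events: dict[str, pd.DataFrame]


def prepare_splits(
    cohort: GroundTruthCohort,
    tasks: list[str] | None = None,
    segment_len: int = 262,
    val_fraction: float = 0.1,
) -> tuple[list[ParticipantSplit], NormalizationStats]:
    """Normalize BOLD with training-half stats, split train/test, and segment.

    Validation = the last ``val_fraction`` of each participant's training
    segments (strictly inside the training half).
    """
    cfg = cohort.cfg
    tasks = tasks or cfg.tasks
    train_pool = []
    half_steps: dict[str, int] = {}
    for task in tasks:
        n = cohort.participants[0].sessions[task].n_steps
        half_steps[task] = n // 2
        for p in cohort.participants:
            train_pool.append(
                RegionTimeSeries(
                    p.sessions[task].bold[: half_steps[task]].T,
                    cfg.step_s,
                    cfg.region_labels,
                )
            )
    norm = fit_normalization(train_pool)

    splits = []
    for p in cohort.participants:
        train_segs: list[MultimodalSequence] = []
        val_segs: list[MultimodalSequence] = []
        test, test_events, train_events = {}, {}, {}
        for task in tasks:
            seq = p.sessions[task]
            normalized = MultimodalSequence(
                sensory=seq.sensory,
                condition=seq.condition,
                action=seq.action,
                bold=(seq.bold - norm.mean) / norm.sd,
                step_s=seq.step_s,
                t0_s=seq.t0_s,
            )
            train_dur = half_steps[task] * cfg.step_s
            tr, te = temporal_split(normalized, train_dur)
            segs = segment_sequences(tr, segment_len)
            n_val = max(1, int(np.floor(val_fraction * len(segs)))) if len(segs) > 1 else 0
            if n_val:
                train_segs.extend(segs[:-n_val])
                val_segs.extend(segs[-n_val:])
            else:
                train_segs.extend(segs)
            test[task] = te
            test_events[task] = shift_events(p.events[task], te.t0_s, train_dur)
            train_events[task] = shift_events(p.events[task], 0.0, train_dur)
        splits.append(
            ParticipantSplit(
                rsfcm=p.rsfcm.edges.copy(),
                train_segments=train_segs,
                val_segments=val_segs,
                test=test,
                test_events=test_events,
                train_events=train_events,
            )
        )
    return splits, norm


# -- vectorized engine --------------------------------------------------------


def _stack(segments_per_p: list[list[MultimodalSequence]]):
    """Stack segments of many participants into batch arrays plus a participant map."""
    inputs, actions, bolds, pmap = [], [], [], []
    for p_idx, segs in enumerate(segments_per_p):
        for seg in segs:
            inputs.append(seg.inputs())
            actions.append(seg.action)
            bolds.append(seg.bold)
            pmap.append(p_idx)
    return (
        np.stack(inputs),
        np.stack(actions),
        np.stack(bolds),
        np.asarray(pmap, dtype=int),
    )


def _theta_views(theta: np.ndarray, cfg: ModelConfig) -> dict[str, np.ndarray]:
    slices = param_slices(cfg)
    return {
        name: theta[:, sl].reshape((theta.shape[0],) + shape)
        for name, (sl, shape) in slices.items()
    }


def _batched_rollout(views: dict[str, np.ndarray], pmap: np.ndarray, inputs: np.ndarray):
    """Forward pass over a (B, T, n_in) batch with per-participant weights."""
    W_ih = views["W_ih"][pmap]
    b_ih = views["b_ih"][pmap]
    W_hh = views["W_hh"][pmap]
    b_hh = views["b_hh"][pmap]
    W_ho = views["W_ho"][pmap]
    b_ho = views["b_ho"][pmap]

    B, T, _ = inputs.shape
    H = W_hh.shape[1]
    drive = np.einsum("bhi,bti->bth", W_ih, inputs) + (b_ih + b_hh)[:, None, :]
    hidden = np.empty((B, T, H))
    h = np.zeros((B, H))
    for t in range(T):
        h = np.tanh(drive[:, t] + np.einsum("bij,bj->bi", W_hh, h))
        hidden[:, t] = h
    Y = np.einsum("boh,bth->bto", W_ho, hidden) + b_ho[:, None, :]
    if not np.isfinite(Y).all():
        raise FloatingPointError("non-finite rollout output")
    return hidden, Y


def _loss_and_grad_Y(
    Y: np.ndarray, actions: np.ndarray, bolds: np.ndarray,
    loss_cfg: LossConfig, n_action: int,
) -> tuple[tuple[float, float, float], np.ndarray]:
    """Next-step-aligned loss: Y[:, :-1] predicts targets at steps 1..T-1."""
    z = Y[:, :-1, :n_action]
    a = actions[:, 1:]
    bp = Y[:, :-1, n_action:]
    b = bolds[:, 1:]
    n_a = max(z.size, 1)
    n_b = max(bp.size, 1)
    l_action = loss_cfg.lambda_action * float(np.sum(softplus(z) - a * z)) / n_a
    l_bold = loss_cfg.lambda_bold * float(np.sum((bp - b) ** 2)) / n_b
    dY = np.zeros_like(Y)
    dY[:, :-1, :n_action] = loss_cfg.lambda_action * (sigmoid(z) - a) / n_a
    dY[:, :-1, n_action:] = loss_cfg.lambda_bold * 2.0 * (bp - b) / n_b
    return (l_action + l_bold, l_action, l_bold), dY


def _batched_backward(
    views: dict[str, np.ndarray], pmap: np.ndarray, inputs: np.ndarray,
    hidden: np.ndarray, dY: np.ndarray, n_participants: int, cfg: ModelConfig,
) -> np.ndarray:
    """BPTT; returns per-participant packed gradients (n_participants, n_params)."""
    W_hh = views["W_hh"][pmap]
    W_ho = views["W_ho"][pmap]

    B, T, H = hidden.shape
    dW_ho = np.einsum("bto,bth->boh", dY, hidden)
    db_ho = dY.sum(axis=1)
    dH = np.einsum("boh,bto->bth", W_ho, dY)

    dpre = np.empty_like(hidden)
    dh_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        dh = dH[:, t] + dh_next
        dpre[:, t] = dh * (1.0 - hidden[:, t] ** 2)
        dh_next = np.einsum("bij,bi->bj", W_hh, dpre[:, t])

    h_prev = np.concatenate([np.zeros((B, 1, H)), hidden[:, :-1]], axis=1)
    dW_ih = np.einsum("bth,bti->bhi", dpre, inputs)
    db_ih = dpre.sum(axis=1)
    dW_hh = np.einsum("bth,btj->bhj", dpre, h_prev)

    # scatter-add segment gradients onto participants, in packing order
    n_params = count_main_params(cfg)
    dtheta = np.zeros((n_participants, n_params))
    slices = param_slices(cfg)
    flat = {
        "W_ih": dW_ih.reshape(B, -1), "b_ih": db_ih,
        "W_hh": dW_hh.reshape(B, -1), "b_hh": db_ih,
        "W_ho": dW_ho.reshape(B, -1), "b_ho": db_ho,
    }
    for name, (sl, _) in slices.items():
        np.add.at(dtheta[:, sl], pmap, flat[name])
    return dtheta


class Adam:
    """Minimal Adam optimizer over a dict of arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


def _eval_loss(
    hp: HypernetParams, model_cfg: ModelConfig, X: np.ndarray,
    segments_per_p: list[list[MultimodalSequence]], loss_cfg: LossConfig,
) -> tuple[float, float, float]:
    if not any(segments_per_p):
        return (np.nan, np.nan, np.nan)
    present = [i for i, segs in enumerate(segments_per_p) if segs]
    theta = hypernet_forward(X[present], hp, model_cfg, dropout_on=False)
    views = _theta_views(theta, model_cfg)
    inputs, actions, bolds, pmap = _stack([segments_per_p[i] for i in present])
    _, Y = _batched_rollout(views, pmap, inputs)
    losses, _ = _loss_and_grad_Y(Y, actions, bolds, loss_cfg, model_cfg.n_action)
    return losses


def train(
    splits: list[ParticipantSplit],
    model_cfg: ModelConfig,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainConfig | None = None,
    init: HypernetParams | None = None,
    verbose: bool = False,
    probe_epoch: int | None = None,
    probe=None,
    post_probe_lr: float | None = None,
    opt: "Adam | None" = None,
) -> tuple[HypernetParams, TrainingLog]:
    """Optimize the hypernetwork end to end; deterministic given the seed.

    Batches sample participants; each selected participant contributes all of
    its training segments. Early stopping monitors the validation loss (last
    fraction of each participant's training segments).

    If ``probe`` is given, it is called as ``probe(hp)`` once after
    ``probe_epoch`` epochs; a falsy return aborts the run. On a passing probe
    the optimizer keeps its state (resetting Adam mid-run destabilizes sharp
    solutions) and, when ``post_probe_lr`` is set, continues at that lower
    learning rate.

    Passing ``opt`` (with ``init``) resumes optimization with Adam moments
    intact, enabling chunked training without mid-run state resets; the
    optimizer's learning rate is refreshed from ``train_cfg.lr``.
    """
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainConfig()
    if not splits or not any(s.train_segments for s in splits):
        raise ValueError("need ≥ 1 participant with ≥ 1 training segment")
    rng = np.random.default_rng(train_cfg.seed)

    X = np.stack([s.rsfcm for s in splits])
    if X.shape[1] != model_cfg.n_in:
        raise ValueError(f"rsFCM length {X.shape[1]} but config expects {model_cfg.n_in}")
    hp = (init.copy() if init is not None else init_hypernet(model_cfg, rng))
    params = hp.as_dict()
    if opt is None:
        opt = Adam(params, train_cfg.lr)
    else:
        opt.lr = train_cfg.lr

    train_segs = [s.train_segments for s in splits]
    val_segs = [s.val_segments for s in splits]
    P = len(splits)
    log = TrainingLog()
    best_val = np.inf
    best_params = hp.copy()
    patience_left = train_cfg.early_stop_patience
    t_start = time.perf_counter()

    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(P)
        ep_losses = []
        for start in range(0, P, train_cfg.batch_size):
            batch = order[start:start + train_cfg.batch_size]
            batch = [i for i in batch if train_segs[i]]
            if not batch:
                continue
            theta, cache = hypernet_forward(
                X[batch], hp, model_cfg, dropout_on=True, seed=rng, return_cache=True
            )
            views = _theta_views(theta, model_cfg)
            inputs, actions, bolds, pmap = _stack([train_segs[i] for i in batch])
            hidden, Y = _batched_rollout(views, pmap, inputs)
            losses, dY = _loss_and_grad_Y(Y, actions, bolds, loss_cfg, model_cfg.n_action)
            if not np.isfinite(losses[0]):
                raise FloatingPointError(f"divergent loss at epoch {epoch}")
            dtheta = _batched_backward(
                views, pmap, inputs, hidden, dY, len(batch), model_cfg
            )
            grads, _ = hypernet_backward(dtheta, cache, hp)
            opt.step(params, grads)
            ep_losses.append(losses)

        tr = tuple(float(np.mean([l[i] for l in ep_losses])) for i in range(3))
        va = _eval_loss(hp, model_cfg, X, val_segs, loss_cfg)
        log.epochs.append(epoch)
        log.train_total.append(tr[0])
        log.train_action.append(tr[1])
        log.train_bold.append(tr[2])
        log.val_total.append(va[0])
        log.val_action.append(va[1])
        log.val_bold.append(va[2])
        if verbose:
            print(f"epoch {epoch:4d}  train {tr[0]:.5f}  val {va[0] if va[0] == va[0] else float('nan'):.5f}")

        if probe is not None and probe_epoch is not None and epoch + 1 == probe_epoch:
            if not probe(hp):
                log.stop_epoch = epoch
                break
            if post_probe_lr is not None:
                opt.lr = post_probe_lr

        monitor = va[0] if np.isfinite(va[0]) else tr[0]
        if monitor < best_val - 1e-12:
            best_val = monitor
            best_params = hp.copy()
            patience_left = train_cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                log.stop_epoch = epoch
                break
    if log.stop_epoch < 0:
        log.stop_epoch = log.epochs[-1] if log.epochs else -1
    log.wall_time_s = time.perf_counter() - t_start
    return (best_params if train_cfg.restore_best else hp), log


# -- evaluation ---------------------------------------------------------------


def evaluate(
    hp: HypernetParams,
    model_cfg: ModelConfig,
    splits: list[ParticipantSplit],
    tasks: list[str] | None = None,
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Per-participant concordance, predicted/observed mean RT, mean BOLD, plus
    cohort-level Pearson correlations of RT and of per-(participant, region,
    task) BOLD means."""
    if not splits:
        raise ValueError("empty evaluation set")
    tasks = tasks or list(splits[0].test.keys())
    rows = []
    bold_pairs: list[tuple[float, float]] = []
    for i, s in enumerate(splits):
        params = generate_main_params(s.rsfcm, hp, model_cfg)
        for task in tasks:
            seq = s.test[task]
            events = s.test_events[task]
            if events.empty:
                continue
            result = rnn_rollout(params, seq.inputs())
            pred_action, pred_bold = predicted_series(result)
            obs_choices = task_codec.decode_choices(
                seq.action, events, task, threshold, seq.step_s
            )
            pred_choices = task_codec.decode_choices(
                pred_action, events, task, threshold, seq.step_s
            )
            conc = task_codec.concordance_rate(pred_choices, obs_choices)
            obs_rt, obs_missing = task_codec.extract_reaction_times(
                seq.action, events, threshold, seq.step_s
            )
            pred_rt, pred_missing = task_codec.extract_reaction_times(
                pred_action, events, threshold, seq.step_s
            )
            mean_bold_pred = np.nanmean(pred_bold, axis=0)
            mean_bold_obs = seq.bold.mean(axis=0)
            bold_pairs.extend(zip(mean_bold_obs, mean_bold_pred))
            rows.append(
                {
                    "participant": i,
                    "task": task,
                    "concordance": conc,
                    "obs_mean_rt_ms": float(np.mean(obs_rt)) if obs_rt.size else np.nan,
                    "pred_mean_rt_ms": float(np.mean(pred_rt)) if pred_rt.size else np.nan,
                    "pred_rt_missing": pred_missing,
                    "obs_rt_missing": obs_missing,
                }
            )
    table = pd.DataFrame(rows)
    summary: dict = {"n_rows": len(table)}
    ok = table.dropna(subset=["obs_mean_rt_ms", "pred_mean_rt_ms"])
    summary["concordance_mean"] = float(table["concordance"].mean())
    if len(ok) >= 3:
        r, p = sp_stats.pearsonr(ok["obs_mean_rt_ms"], ok["pred_mean_rt_ms"])
        summary["rt_pearson_r"] = float(r)
        summary["rt_pearson_p"] = float(p)
    if len(bold_pairs) >= 3:
        arr = np.asarray(bold_pairs)
        r, p = sp_stats.pearsonr(arr[:, 0], arr[:, 1])
        summary["bold_mean_pearson_r"] = float(r)
    return table, summary
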