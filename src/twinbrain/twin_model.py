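"""Hypernetwork MLP + vanilla-RNN main network, with hand-written backprop.

The hypernetwork maps a participant's rsFCM vector to the packed parameter
vector of the main network:

    h1 = Mish(W1 x + b1)          (input dropout applied to x during training)
    h2 = Mish(W2 h1 + b2)
    y  = W3 h2 + b3               (y = packed main-network parameters)

The main network is a vanilla RNN rolled out over the sensory + task-condition
input:

    h_t = tanh(W_ih x_t + b_ih + W_hh h_{t-1} + b_hh)
    y_t = W_ho h_t + b_ho

``y_t`` is the prediction for step t+1; its first ``n_action`` dims pass
through a logistic sigmoid into action probabilities (so a binary
cross-entropy loss applies), the remaining ``n_bold`` dims are returned raw.

No autograd framework is available in this environment, so forward passes
cache what the matching ``*_backward`` functions need; gradients are verified
against finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

PACK_ORDER = ("W_ih", "b_ih", "W_hh", "b_hh", "W_ho", "b_ho")


@dataclass
class ModelConfig:
    n_in: int  # rsFCM vector length
    n_hidden_hyper: int = 200
    dropout: float = 0.1
    n_sensor_plus_cond: int = 9  # 8 sensory + 1 task condition
    n_hidden_main: int = 400
    n_action: int = 3
    n_bold: int = 20

    def __post_init__(self) -> None:
        for name in ("n_in", "n_hidden_hyper", "n_sensor_plus_cond", "n_hidden_main",
                     "n_action"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1, got {getattr(self, name)}")
        if self.n_bold < 0:
            raise ValueError(f"n_bold must be ≥ 0, got {self.n_bold}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")

    @property
    def n_out(self) -> int:
        return self.n_action + self.n_bold

    def to_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_hidden_hyper": self.n_hidden_hyper,
            "dropout": self.dropout,
            "n_sensor_plus_cond": self.n_sensor_plus_cond,
            "n_hidden_main": self.n_hidden_main,
            "n_action": self.n_action,
            "n_bold": self.n_bold,
        }


def count_main_params(cfg: ModelConfig) -> int:
    """Total learnable scalars of the main network: |W_ih|+|b_ih|+|W_hh|+|b_hh|+|W_ho|+|b_ho|."""
    h, s, o = cfg.n_hidden_main, cfg.n_sensor_plus_cond, cfg.n_out
    return h * s + h + h * h + h + o * h + o


def param_slices(cfg: ModelConfig) -> dict[str, tuple[slice, tuple[int, ...]]]:
    """Packing layout: name -> (slice into the packed vector, view shape)."""
    h, s, o = cfg.n_hidden_main, cfg.n_sensor_plus_cond, cfg.n_out
    shapes = {
        "W_ih": (h, s), "b_ih": (h,),
        "W_hh": (h, h), "b_hh": (h,),
        "W_ho": (o, h), "b_ho": (o,),
    }
    out, offset = {}, 0
    for name in PACK_ORDER:
        size = int(np.prod(shapes[name]))
        out[name] = (slice(offset, offset + size), shapes[name])
        offset += size
    return out


def layout_hash(cfg: ModelConfig) -> str:
    """Stable identifier of the packing coordinate system for a config."""
    import hashlib

    spec = json.dumps(
        {"order": PACK_ORDER, "dims": [cfg.n_sensor_plus_cond, cfg.n_hidden_main,
                                       cfg.n_action, cfg.n_bold]},
        sort_keys=True,
    )
    return hashlib.sha256(spec.encode()).hexdigest()[:16]


@dataclass
class MainNetParams:
    """Packed main-network parameter vector plus structured views."""

    packed: np.ndarray
    cfg: ModelConfig

    def __post_init__(self) -> None:
        expected = count_main_params(self.cfg)
        if self.packed.shape != (expected,):
            raise ValueError(
                f"packed vector has shape {self.packed.shape}, expected ({expected},)"
            )

    def view(self, name: str) -> np.ndarray:
        sl, shape = param_slices(self.cfg)[name]
        return self.packed[sl].reshape(shape)

    @property
    def W_ih(self) -> np.ndarray:
        return self.view("W_ih")

    @property
    def b_ih(self) -> np.ndarray:
        return self.view("b_ih")

    @property
    def W_hh(self) -> np.ndarray:
        return self.view("W_hh")

    @property
    def b_hh(self) -> np.ndarray:
        return self.view("b_hh")

    @property
    def W_ho(self) -> np.ndarray:
        return self.view("W_ho")

    @property
    def b_ho(self) -> np.ndarray:
        return self.view("b_ho")


def pack_views(cfg: ModelConfig, **views: np.ndarray) -> MainNetParams:
    """Inverse of the structured views: pack named arrays into a flat vector."""
    packed = np.empty(count_main_params(cfg))
    slices = param_slices(cfg)
    for name in PACK_ORDER:
        sl, shape = slices[name]
        arr = np.asarray(views[name], dtype=float)
        if arr.shape != shape:
            raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        packed[sl] = arr.ravel()
    return MainNetParams(packed, cfg)


# -- activations --------------------------------------------------------------


def softplus(u: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, u)


def mish(u: np.ndarray) -> np.ndarray:
    """u · tanh(softplus(u)), numerically stable for large |u|."""
    return u * np.tanh(softplus(u))


def mish_grad(u: np.ndarray) -> np.ndarray:
    sp = softplus(u)
    t = np.tanh(sp)
    sig = _sigmoid(u)
    return t + u * (1.0 - t * t) * sig


def _sigmoid(u: np.ndarray) -> np.ndarray:
    out = np.empty_like(u, dtype=float)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


sigmoid = _sigmoid


# -- hypernetwork -------------------------------------------------------------


@dataclass
class HypernetParams:
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray

    def names(self) -> tuple[str, ...]:
        return ("W1", "b1", "W2", "b2", "W3", "b3")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in self.names()}

    def copy(self) -> "HypernetParams":
        return HypernetParams(**{n: getattr(self, n).copy() for n in self.names()})


def init_hypernet(
    cfg: ModelConfig,
    seed: int | np.random.Generator = 0,
    action_bias_logit: float | None = None,
) -> HypernetParams:
    """Scaled-Gaussian init; the output layer's gain is shrunk by 1/sqrt(n_hidden_hyper)
    so the generated RNN weights start small.

    ``action_bias_logit`` seeds the generated action output biases (via the
    hypernetwork's output bias b3) at a fixed logit. Starting them near the
    press base rate instead of 0 (probability 0.5) removes the violent
    suppress-everything transient at the start of training, which otherwise
    tends to trap optimization in a timid all-zeros equilibrium.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    nh = cfg.n_hidden_hyper
    n_params = count_main_params(cfg)
    hp = HypernetParams(
        W1=rng.normal(0.0, 1.0 / np.sqrt(cfg.n_in), (nh, cfg.n_in)),
        b1=np.zeros(nh),
        W2=rng.normal(0.0, 1.0 / np.sqrt(nh), (nh, nh)),
        b2=np.zeros(nh),
        W3=rng.normal(0.0, 1.0 / nh, (n_params, nh)),
        b3=np.zeros(n_params),
    )
    if action_bias_logit is not None:
        sl, _ = param_slices(cfg)["b_ho"]
        hp.b3[sl.start:sl.start + cfg.n_action] = action_bias_logit
    return hp


def hypernet_forward(
    x: np.ndarray,
    hp: HypernetParams,
    cfg: ModelConfig,
    dropout_on: bool = False,
    seed: int | np.random.Generator = 0,
    return_cache: bool = False,
):
    """Map rsFCM vector(s) to packed main-network parameter vector(s).

    ``x`` may be a single vector (n_in,) or a batch (P, n_in). Input dropout
    (inverted, rate ``cfg.dropout``) is applied only when ``dropout_on``.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != cfg.n_in:
        raise ValueError(f"rsFCM length {X.shape[1]} but config expects {cfg.n_in}")

    if dropout_on and cfg.dropout > 0.0:
        rng = (np.random.default_rng(seed)
               if not isinstance(seed, np.random.Generator) else seed)
        mask = (rng.random(X.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
    else:
        mask = np.ones_like(X)
    Xd = X * mask

    u1 = Xd @ hp.W1.T + hp.b1
    h1 = mish(u1)
    u2 = h1 @ hp.W2.T + hp.b2
    h2 = mish(u2)
    Y = h2 @ hp.W3.T + hp.b3

    if not return_cache:
        return Y[0] if single else Y
    cache = {"Xd": Xd, "mask": mask, "u1": u1, "h1": h1, "u2": u2, "h2": h2,
             "single": single}
    return (Y[0] if single else Y), cache


def hypernet_backward(
    dY: np.ndarray, cache: dict, hp: HypernetParams
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Backprop ``dL/dY`` through the hypernetwork.

    Returns (parameter gradients, dL/dx). Respects the dropout mask stored in
    the forward cache.
    """
    dY = np.asarray(dY, dtype=float)
    if dY.ndim == 1:
        dY = dY[None, :]
    grads = {}
    grads["W3"] = dY.T @ cache["h2"]
    grads["b3"] = dY.sum(axis=0)
    dh2 = dY @ hp.W3
    du2 = dh2 * mish_grad(cache["u2"])
    grads["W2"] = du2.T @ cache["h1"]
    grads["b2"] = du2.sum(axis=0)
    dh1 = du2 @ hp.W2
    du1 = dh1 * mish_grad(cache["u1"])
    grads["W1"] = du1.T @ cache["Xd"]
    grads["b1"] = du1.sum(axis=0)
    dx = (du1 @ hp.W1) * cache["mask"]
    if cache["single"]:
        dx = dx[0]
    return grads, dx


def generate_main_params(
    x: np.ndarray, hp: HypernetParams, cfg: ModelConfig
) -> MainNetParams:
    """Evaluation-mode (dropout off) hypernetwork pass returning structured params."""
    packed = hypernet_forward(x, hp, cfg, dropout_on=False)
    return MainNetParams(np.asarray(packed, dtype=float), cfg)


# -- main network rollout -----------------------------------------------------


@dataclass
class RolloutResult:
    hidden: np.ndarray  # T x n_hidden_main, entries in (-1, 1)
    action_prob: np.ndarray  # T x n_action, in (0, 1); prediction for step t+1
    bold_pred: np.ndarray  # T x n_bold; prediction for step t+1
    action_logit: np.ndarray  # T x n_action, pre-sigmoid


def rnn_rollout(
    params: MainNetParams,
    inputs: np.ndarray,
    h0: np.ndarray | None = None,
    return_cache: bool = False,
):
    """Roll the vanilla RNN over ``inputs`` (T × n_sensor_plus_cond)."""
    cfg = params.cfg
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 2 or inputs.shape[1] != cfg.n_sensor_plus_cond:
        raise ValueError(
            f"inputs must be T × {cfg.n_sensor_plus_cond}, got {inputs.shape}"
        )
    T = inputs.shape[0]
    H = cfg.n_hidden_main
    h = np.zeros(H) if h0 is None else np.asarray(h0, dtype=float)
    if h.shape != (H,):
        raise ValueError(f"h0 must have length {H}, got {h.shape}")

    W_ih, b_ih = params.W_ih, params.b_ih
    W_hh, b_hh = params.W_hh, params.b_hh
    W_ho, b_ho = params.W_ho, params.b_ho

    hidden = np.empty((T, H))
    drive = inputs @ W_ih.T + b_ih + b_hh
    for t in range(T):
        h = np.tanh(drive[t] + W_hh @ h)
        if not np.isfinite(h).all():
            raise FloatingPointError(f"non-finite hidden state at step {t}")
        hidden[t] = h

    Y = hidden @ W_ho.T + b_ho
    logits = Y[:, : cfg.n_action]
    result = RolloutResult(
        hidden=hidden,
        action_prob=_sigmoid(logits),
        bold_pred=Y[:, cfg.n_action:],
        action_logit=logits,
    )
    if not return_cache:
        return result
    h_prev = np.vstack([np.zeros(H) if h0 is None else h0, hidden[:-1]])
    return result, {"inputs": inputs, "hidden": hidden, "h_prev": h_prev}


def rollout_backward(
    dY: np.ndarray, cache: dict, params: MainNetParams
) -> tuple[np.ndarray, np.ndarray]:
    """Backprop ``dL/dY`` (T × n_out, gradients w.r.t. the linear outputs y_t)
    through the rollout.

    Returns (dL/d packed params, dL/d inputs).
    """
    cfg = params.cfg
    hidden, h_prev, inputs = cache["hidden"], cache["h_prev"], cache["inputs"]
    T = hidden.shape[0]
    dY = np.asarray(dY, dtype=float)

    dW_ho = dY.T @ hidden
    db_ho = dY.sum(axis=0)
    dH = dY @ params.W_ho

    W_hh = params.W_hh
    dpre = np.empty_like(hidden)
    dh_next = np.zeros(cfg.n_hidden_main)
    for t in range(T - 1, -1, -1):
        dh = dH[t] + dh_next
        dpre[t] = dh * (1.0 - hidden[t] ** 2)
        dh_next = W_hh.T @ dpre[t]

    dW_ih = dpre.T @ inputs
    db_ih = dpre.sum(axis=0)
    dW_hh = dpre.T @ h_prev
    db_hh = db_ih.copy()
    d_inputs = dpre @ params.W_ih

    dpacked = pack_views(
        cfg, W_ih=dW_ih, b_ih=db_ih, W_hh=dW_hh, b_hh=db_hh, W_ho=dW_ho, b_ho=db_ho
    ).packed
    return dpacked, d_inputs


def predicted_series(result: RolloutResult) -> tuple[np.ndarray, np.ndarray]:
    """Align predictions with the input time base.

    The rollout's output at index t is the prediction for step t+1; this
    shifts both channels forward one step (a zero/NaN leading row) so the
    returned arrays share the time base of the input sequence.
    """
    T = result.action_prob.shape[0]
    action = np.zeros((T, result.action_prob.shape[1]))
    action[1:] = result.action_prob[:-1]
    bold = np.full((T, result.bold_pred.shape[1]), np.nan)
    bold[1:] = result.bold_pred[:-1]
    return action, bold


# -- checkpoints --------------------------------------------------------------


def save_checkpoint(path: str, hp: HypernetParams, cfg: ModelConfig) -> None:
    """Single-archive checkpoint: config JSON + named parameter arrays."""
    np.savez(
        path,
        config=json.dumps(cfg.to_dict()),
        **hp.as_dict(),
    )


def load_checkpoint(path: str) -> tuple[HypernetParams, ModelConfig]:
    with np.load(path, allow_pickle=False) as data:
        cfg = ModelConfig(**json.loads(str(data["config"])))
        hp = HypernetParams(**{n: data[n] for n in ("W1", "b1", "W2", "b2", "W3", "b3")})
    return hp, cfg
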