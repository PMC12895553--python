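"""SmoothGrad connectome-edge targeting and weight-space intervention simulation.

SmoothGrad averages, over noise-perturbed copies of a participant's rsFCM, the
gradient of the first latent score z1 (the projection of the standardized
hypernetwork output onto a PLS direction v) with respect to the input edges.
Edge targets are the entries whose cohort-averaged gradient deviates from the
map mean by more than a threshold number of SDs, split into strengthen (g > 0)
and weaken (g < 0) lists.

The intervention itself adds the displacement α·v to a participant's packed
main-network weights. v lives in *standardized* parameter space (PLS
standardizes W_main columns), so the displacement is mapped back to raw
parameter units by elementwise multiplication with the stored column SDs
before the update packedʹ = packed + α·v_raw; α is in SD(z1) units and the
default manipulation intensity is twice the SD of z1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import task_codec
from .indicators_pls import (
    PlsResult,
    affective_indicator,
    cognitive_indicator,
)
from .preprocess import RsFcm
from .twin_model import (
    HypernetParams,
    MainNetParams,
    ModelConfig,
    generate_main_params,
    hypernet_backward,
    hypernet_forward,
    predicted_series,
    rnn_rollout,
)


@dataclass
class SmoothGradConfig:
    n_samples: int = 100
    noise_level: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be ≥ 1")
        if self.noise_level < 0:
            raise ValueError("noise_level must be ≥ 0")


@dataclass
class GradientMap:
    gradients: np.ndarray  # per-edge mean gradient, same edge order as RsFcm
    cohort_averaged: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.gradients).all():
            raise ValueError("non-finite gradient map")


@dataclass
class InterventionSpec:
    pls: PlsResult
    alpha: float  # manipulation intensity; default 2·SD(z1) chosen by callers
    layout_hash: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")


def default_alpha(pls: PlsResult, sd_multiple: float = 2.0) -> float:
    """α = (multiple)·SD(z1); the conventional setting is twice the SD."""
    return sd_multiple * float(np.std(pls.z1))


def smoothgrad_edges(
    hp: HypernetParams,
    model_cfg: ModelConfig,
    rsfcm: RsFcm | np.ndarray,
    pls: PlsResult,
    cfg: SmoothGradConfig | None = None,
) -> GradientMap:
    """Mean gradient of z1 w.r.t. the rsFCM edges over noise-perturbed inputs.

    Noise is N(0, (noise_level · SD(x))²) with SD(x) taken over all edges of
    the participant's rsFCM; the hypernetwork output is standardized with the
    stored PLS stats before projecting onto v (dropout stays off).
    """
    cfg = cfg or SmoothGradConfig()
    if pls.w_sd is None or pls.w_mean is None:
        raise ValueError("PLS result lacks standardization stats")
    x = rsfcm.edges if isinstance(rsfcm, RsFcm) else np.asarray(rsfcm, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    noise_sd = cfg.noise_level * float(np.std(x))
    # dz1/d(theta) for standardized outputs: v_j / sd_j (zero-SD columns excluded)
    safe_sd = np.where(pls.w_sd == 0, 1.0, pls.w_sd)
    dtheta = np.where(pls.w_sd == 0, 0.0, pls.v / safe_sd)

    acc = np.zeros_like(x)
    for _ in range(cfg.n_samples):
        xt = x + rng.normal(0.0, noise_sd, x.shape) if noise_sd > 0 else x
        _, cache = hypernet_forward(xt, hp, model_cfg, dropout_on=False, return_cache=True)
        _, dx = hypernet_backward(dtheta, cache, hp)
        acc += dx
    return GradientMap(gradients=acc / cfg.n_samples, cohort_averaged=False)


def cohort_gradient_map(maps: list[GradientMap]) -> GradientMap:
    """Cohort-level map = mean of per-participant maps."""
    if not maps:
        raise ValueError("no gradient maps")
    return GradientMap(
        gradients=np.mean([m.gradients for m in maps], axis=0), cohort_averaged=True
    )


def select_top_edges(
    gmap: GradientMap,
    edge_index: list[tuple[int, int]],
    sd_threshold: float = 2.5,
    region_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Edges whose gradient deviates from the map mean by more than
    ``sd_threshold`` SDs, split into strengthen (g > 0) / weaken (g < 0) with
    magnitudes in SD units."""
    g = gmap.gradients
    mean, sd = float(g.mean()), float(g.std())
    if sd == 0:
        keep = np.zeros(g.shape, dtype=bool) if sd_threshold > 0 else np.ones(g.shape, bool)
        dev = np.zeros_like(g)
    else:
        dev = (g - mean) / sd
        keep = np.abs(dev) > sd_threshold
    rows = []
    for k in np.nonzero(keep)[0]:
        i, j = edge_index[k]
        rows.append(
            {
                "edge": k,
                "region_i": region_labels[i] if region_labels else str(i),
                "region_j": region_labels[j] if region_labels else str(j),
                "gradient": g[k],
                "deviation_sd": abs(dev[k]),
                "direction": "strengthen" if g[k] > 0 else "weaken",
            }
        )
    return pd.DataFrame(
        rows, columns=["edge", "region_i", "region_j", "gradient", "deviation_sd",
                       "direction"]
    ).sort_values("deviation_sd", ascending=False, ignore_index=True) if rows else \
        pd.DataFrame(columns=["edge", "region_i", "region_j", "gradient",
                              "deviation_sd", "direction"])


def destandardize_direction(pls: PlsResult) -> np.ndarray:
    """Map v from standardized-parameter space to raw units (elementwise × column SD).

    The displacement α·v lives in the standardized space where PLS and the z1
    score are defined (α is in SD(z1) units); mapping the *whole* displacement
    back — Δw_j = α·v_j·sd_j — shifts z1 by exactly α·‖v‖² = α. Renormalizing
    to a unit raw vector would break that correspondence, so we don't.
    """
    v_raw = pls.v * pls.w_sd
    if np.linalg.norm(v_raw) == 0:
        raise ValueError("direction vanishes after de-standardization")
    return v_raw


def perturb_weights(params: MainNetParams, spec: InterventionSpec) -> MainNetParams:
    """packedʹ = packed + α·v_raw (v de-standardized; layout verified by hash)."""
    from .twin_model import layout_hash as _layout_hash

    expected = _layout_hash(params.cfg)
    if spec.layout_hash and spec.layout_hash != expected:
        raise ValueError(
            f"layout-hash mismatch: vector built for {spec.layout_hash}, "
            f"model uses {expected}"
        )
    if spec.pls.v.shape != params.packed.shape:
        raise ValueError(
            f"direction length {spec.pls.v.shape[0]} does not match "
            f"{params.packed.shape[0]} parameters"
        )
    if spec.alpha == 0.0:
        return MainNetParams(params.packed.copy(), params.cfg)
    v_raw = destandardize_direction(spec.pls)
    return MainNetParams(params.packed + spec.alpha * v_raw, params.cfg)


@dataclass
class InterventionOutcome:
    """Per-participant indicator values pre/post manipulation.

    ``pre``/``post`` map indicator kind ("affective", "cognitive") to arrays
    with one value per participant; participants with no valid RT carry NaN in
    the cognitive entries and are listed in ``excluded`` (they are left out of
    effect-size statistics, with the count reported).
    """

    pre: dict[str, np.ndarray]
    post: dict[str, np.ndarray]
    excluded: list[int] = field(default_factory=list)


def _indicators_for(
    params_per_p: list[MainNetParams],
    splits,
    region_labels: list[str],
    tasks: list[str],
    threshold: float,
) -> tuple[dict[str, np.ndarray], list[int]]:
    from .task_codec import EF_TASK

    pred_bold_ef, ef_events = [], []
    pred_actions: dict[str, list[np.ndarray]] = {t: [] for t in tasks}
    events_by_task: dict[str, list[pd.DataFrame]] = {t: [] for t in tasks}
    for params, s in zip(params_per_p, splits):
        for task in tasks:
            seq = s.test[task]
            result = rnn_rollout(params, seq.inputs())
            action, bold = predicted_series(result)
            pred_actions[task].append(action)
            events_by_task[task].append(s.test_events[task])
            if task == EF_TASK:
                pred_bold_ef.append(bold)
                ef_events.append(s.test_events[task])

    out: dict[str, np.ndarray] = {}
    excluded: list[int] = []
    if EF_TASK in tasks:
        out["affective"] = affective_indicator(
            pred_bold_ef, ef_events, region_labels, splits[0].test[EF_TASK].step_s
        ).values
    # cognitive indicator: participants with no decodable press get flagged
    values = np.empty(len(params_per_p))
    for i in range(len(params_per_p)):
        try:
            ind = cognitive_indicator(
                {t: [pred_actions[t][i]] for t in tasks},
                {t: [events_by_task[t][i]] for t in tasks},
                threshold,
            )
            values[i] = ind.values[0]
        except ValueError:
            values[i] = np.nan
            excluded.append(i)
    out["cognitive"] = values
    return out, excluded


def simulate_intervention(
    hp: HypernetParams,
    model_cfg: ModelConfig,
    splits,
    spec: InterventionSpec,
    region_labels: list[str],
    tasks: list[str] | None = None,
    threshold: float = 0.5,
) -> InterventionOutcome:
    """Roll out each participant with original and perturbed weights on identical
    sensory inputs; compute both indicators pre and post."""
    tasks = tasks or list(splits[0].test.keys())
    pre_params = [generate_main_params(s.rsfcm, hp, model_cfg) for s in splits]
    post_params = [perturb_weights(p, spec) for p in pre_params]
    pre, excl_pre = _indicators_for(pre_params, splits, region_labels, tasks, threshold)
    post, excl_post = _indicators_for(post_params, splits, region_labels, tasks, threshold)
    return InterventionOutcome(
        pre=pre, post=post, excluded=sorted(set(excl_pre) | set(excl_post))
    )


def effect_sizes(pre: np.ndarray, post: np.ndarray) -> dict:
    """Standardized effects d_i = (pre_i − post_i) / SD_across-participants(pre),
    with the fraction exceeding the Cohen's-d = 0.8 benchmark."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("need matched pre/post values for ≥ 2 participants")
    sd = float(np.std(pre, ddof=1))
    if sd == 0:
        raise ValueError("constant premanipulation values")
    d = (pre - post) / sd
    return {
        "d": d,
        "mean_d": float(np.mean(d)),
        "median_d": float(np.median(d)),
        "frac_large": float(np.mean(np.abs(d) >= 0.8)),
        "pre_sd": sd,
    }
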