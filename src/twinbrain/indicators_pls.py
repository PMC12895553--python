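"""Functional indicators and PLS-derived direction vectors over main-network
parameter space.

Two per-participant indicators summarize the model's task output:

- affective: the face>shape contrast t-statistic of the predicted
  right-amygdala BOLD (GLM with the canonical HRF);
- cognitive: mean reaction time (ms) decoded from the predicted action
  sequences, pooled over the configured tasks (unweighted mean of task means).

The single-component PLS direction v maximizes covariance between the
projection scores z1 = W v and the indicator s, computed in closed form on
standardized data: v = Wᵀs / ‖Wᵀs‖ (no deflation, no further components).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import glm, task_codec
from .regions import right_amygdala_index


@dataclass
class FunctionalIndicator:
    kind: str  # "affective" | "cognitive"
    values: np.ndarray  # one scalar per participant

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError(f"non-finite {self.kind} indicator values")


@dataclass
class PlsResult:
    """Unit coefficient vector over main-network parameters plus latent scores."""

    v: np.ndarray  # unit vector, length n_params_main
    z1: np.ndarray  # per-participant scores on standardized W
    w_mean: np.ndarray  # column standardization stats of W_main
    w_sd: np.ndarray  # zero-variance columns carry sd = 0 (v entry forced to 0)
    s_mean: float
    s_sd: float
    layout_hash: str = ""

    def __post_init__(self) -> None:
        norm = np.linalg.norm(self.v)
        if abs(norm - 1.0) > 1e-10:
            raise ValueError(f"v must be unit length, got ‖v‖ = {norm}")


def affective_indicator(
    bold_pred_per_participant: list[np.ndarray],
    events_per_participant: list[pd.DataFrame],
    region_labels: list[str],
    step_s: float = task_codec.STEP_S,
    dct_cutoff_hz: float = 0.01,
) -> FunctionalIndicator:
    """Per-participant face>shape t-statistic of predicted right-amygdala BOLD."""
    idx = right_amygdala_index(region_labels)
    values = []
    for bold, events in zip(bold_pred_per_participant, events_per_participant):
        y = np.asarray(bold, dtype=float)[:, idx].copy()
        finite = np.isfinite(y)
        if not finite.any():
            raise ValueError("all-NaN predicted BOLD series")
        # a leading NaN row can arise from the next-step prediction shift
        y[~finite] = y[finite][0]
        design = glm.build_design(
            events, len(y), step_s, dct_cutoff_hz, conditions=["face", "shape"]
        )
        fit = glm.fit_glm(design, y)
        values.append(fit.t_stat("face>shape"))
    return FunctionalIndicator("affective", np.asarray(values))


def cognitive_indicator(
    pred_action_per_participant: dict[str, list[np.ndarray]],
    events_per_participant: dict[str, list[pd.DataFrame]],
    threshold: float = 0.5,
    step_s: float = task_codec.STEP_S,
) -> FunctionalIndicator:
    """Mean RT (ms) per participant, pooled over tasks as the unweighted mean
    of task means. Participants with no decodable press in any task raise."""
    tasks = list(pred_action_per_participant.keys())
    n = len(pred_action_per_participant[tasks[0]])
    values = []
    for i in range(n):
        task_means = []
        for task in tasks:
            rts, _ = task_codec.extract_reaction_times(
                pred_action_per_participant[task][i],
                events_per_participant[task][i],
                threshold,
                step_s,
            )
            if rts.size:
                task_means.append(float(np.mean(rts)))
        if not task_means:
            raise ValueError(f"participant {i} has no decodable response in any task")
        values.append(float(np.mean(task_means)))
    return FunctionalIndicator("cognitive", np.asarray(values))


def pls_direction(
    w_main: np.ndarray,
    s: FunctionalIndicator | np.ndarray,
    layout_hash: str = "",
) -> PlsResult:
    """Closed-form single-component PLS direction on standardized data.

    Zero-variance parameter columns are dropped (with a warning) and
    re-inserted as zeros in v.
    """
    import warnings

    W = np.asarray(w_main, dtype=float)
    s_vals = s.values if isinstance(s, FunctionalIndicator) else np.asarray(s, dtype=float)
    if W.ndim != 2 or W.shape[0] < 3:
        raise ValueError("need a participants × n_params matrix with ≥ 3 rows")
    if s_vals.shape != (W.shape[0],):
        raise ValueError("indicator length must equal the number of participants")
    s_mean, s_sd = float(s_vals.mean()), float(s_vals.std())
    if s_sd == 0:
        raise ValueError("constant functional indicator")
    s_std = (s_vals - s_mean) / s_sd

    w_mean = W.mean(axis=0)
    w_sd = W.std(axis=0)
    zero = w_sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance parameter columns dropped from PLS",
            stacklevel=2,
        )
    safe_sd = np.where(zero, 1.0, w_sd)
    Z = (W - w_mean) / safe_sd
    Z[:, zero] = 0.0

    raw = Z.T @ s_std
    norm = np.linalg.norm(raw)
    if norm == 0:
        raise ValueError("indicator is uncorrelated with every parameter column")
    v = raw / norm
    v[zero] = 0.0
    v /= np.linalg.norm(v)
    return PlsResult(
        v=v,
        z1=Z @ v,
        w_mean=w_mean,
        w_sd=np.where(zero, 0.0, w_sd),
        s_mean=s_mean,
        s_sd=s_sd,
        layout_hash=layout_hash,
    )


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj


def correlate_with_measures(
    z1: np.ndarray, measures: pd.DataFrame, fdr_q: float = 0.05
) -> pd.DataFrame:
    """Pearson r + two-sided p per measure column, BH-FDR adjusted across columns.

    Missing values are handled by pairwise deletion; every measure needs ≥ 3
    complete pairs.
    """
    z1 = np.asarray(z1, dtype=float)
    rows = []
    for col in measures.columns:
        y = measures[col].to_numpy(dtype=float)
        mask = np.isfinite(y) & np.isfinite(z1)
        if mask.sum() < 3:
            raise ValueError(f"measure {col!r} has fewer than 3 complete pairs")
        r, p = sp_stats.pearsonr(z1[mask], y[mask])
        rows.append({"measure": col, "n": int(mask.sum()), "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["p_adjusted"] < fdr_q
    return out
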