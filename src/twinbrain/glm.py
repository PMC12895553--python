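"""General linear model of BOLD responses.

Design: per condition a boxcar (trial duration) convolved with the Glover
canonical HRF and with its first temporal derivative; discrete-cosine drift
columns below a cutoff frequency; a constant baseline column. Ordinary least
squares per region; contrast t-statistics; one-sample group t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

HRF_LENGTH_S = 32.0


@dataclass
class GloverParams:
    """Conventional double-gamma parameters (exposed, not hard-coded)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 12.0
    peak_dispersion: float = 0.9
    undershoot_dispersion: float = 0.9
    undershoot_ratio: float = 0.35


def glover_hrf(grid_s: np.ndarray, params: GloverParams | None = None) -> np.ndarray:
    """Glover double-gamma HRF on a uniform grid starting at 0, peak-normalized to 1."""
    grid_s = np.asarray(grid_s, dtype=float)
    if grid_s.size == 0:
        raise ValueError("empty time grid")
    if grid_s[0] != 0.0:
        raise ValueError(f"grid must start at 0, got {grid_s[0]}")
    p = params or GloverParams()
    peak = stats.gamma.pdf(grid_s, a=p.peak_delay_s / p.peak_dispersion,
                           scale=p.peak_dispersion)
    under = stats.gamma.pdf(grid_s, a=p.undershoot_delay_s / p.undershoot_dispersion,
                            scale=p.undershoot_dispersion)
    kernel = peak - p.undershoot_ratio * under
    m = kernel.max()
    if m <= 0:
        raise ValueError("degenerate HRF kernel (non-positive peak)")
    return kernel / m


@dataclass
class GlmDesign:
    X: np.ndarray  # n_scans x p
    column_names: list[str]
    contrasts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.column_names):
            raise ValueError("column_names length must match X columns")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError(
                f"rank-deficient design matrix (columns: {self.column_names})"
            )


@dataclass
class GlmFit:
    beta: np.ndarray
    sigma2: float  # dof-corrected residual variance
    dof: int
    xtx_inv: np.ndarray
    column_names: list[str]
    contrasts: dict[str, np.ndarray]

    def t_stat(self, contrast: str | np.ndarray) -> float:
        c = self.contrasts[contrast] if isinstance(contrast, str) else np.asarray(contrast)
        est = float(c @ self.beta)
        var = self.sigma2 * float(c @ self.xtx_inv @ c)
        if var <= 0.0:
            # perfect fit: infinite-guarded; a contrast estimate at numerical
            # noise level counts as zero
            tol = 1e-8 * max(1.0, float(np.abs(self.beta).max()))
            return float(np.sign(est) * np.inf) if abs(est) > tol else 0.0
        return est / np.sqrt(var)


def dct_drift_count(duration_s: float, cutoff_hz: float) -> int:
    """K = floor(2 · duration · cutoff) DCT drift columns below the cutoff."""
    return int(np.floor(2.0 * duration_s * cutoff_hz))


def condition_boxcar(
    events: pd.DataFrame, condition: str, n_scans: int, step_s: float
) -> np.ndarray:
    """Unit boxcar over each trial's [onset, onset + duration) for one condition."""
    box = np.zeros(n_scans)
    for ev in events[events["trial_type"] == condition].itertuples(index=False):
        a = int(np.floor(ev.onset / step_s + 1e-9))
        b = int(np.floor((ev.onset + ev.duration) / step_s + 1e-9))
        box[max(a, 0):min(b, n_scans)] = 1.0
    return box


def build_design(
    events: pd.DataFrame,
    n_scans: int,
    step_s: float,
    dct_cutoff_hz: float = 0.01,
    conditions: list[str] | None = None,
    hrf_params: GloverParams | None = None,
) -> GlmDesign:
    """HRF + derivative regressors per condition, DCT drift, constant.

    All columns except the constant are mean-centered. Default contrasts are
    ``"<condA>><condB>"`` (+1 / −1 on the two HRF columns) for every ordered
    condition pair.
    """
    if conditions is None:
        conditions = list(dict.fromkeys(events["trial_type"])) if len(events) else []
    bad = events[~events["trial_type"].isin(conditions)] if len(events) else events
    if len(events) and len(bad):
        raise ValueError(f"events outside declared conditions: {set(bad['trial_type'])}")
    if len(events) and (events["onset"] + events["duration"]).max() > n_scans * step_s:
        raise ValueError("events extend past the scan duration")

    hrf_grid = np.arange(0.0, HRF_LENGTH_S + step_s / 2, step_s)
    kernel = glover_hrf(hrf_grid, hrf_params)
    d_kernel = np.gradient(kernel, step_s)

    cols, names = [], []
    for cond in conditions:
        box = condition_boxcar(events, cond, n_scans, step_s)
        cols.append(np.convolve(box, kernel)[:n_scans])
        names.append(f"{cond}_hrf")
        cols.append(np.convolve(box, d_kernel)[:n_scans])
        names.append(f"{cond}_deriv")

    K = dct_drift_count(n_scans * step_s, dct_cutoff_hz)
    t = np.arange(n_scans)
    for k in range(1, K + 1):
        cols.append(np.cos(np.pi * (t + 0.5) * k / n_scans))
        names.append(f"dct_{k}")

    X = np.column_stack(cols) if cols else np.empty((n_scans, 0))
    X = X - X.mean(axis=0, keepdims=True) if X.shape[1] else X
    X = np.column_stack([X, np.ones(n_scans)])
    names.append("constant")

    contrasts = {}
    p = len(names)
    for a in conditions:
        for b in conditions:
            if a == b:
                continue
            c = np.zeros(p)
            c[names.index(f"{a}_hrf")] = 1.0
            c[names.index(f"{b}_hrf")] = -1.0
            contrasts[f"{a}>{b}"] = c
    return GlmDesign(X=X, column_names=names, contrasts=contrasts)


def fit_glm(design: GlmDesign, y: np.ndarray) -> GlmFit:
    """OLS fit of one region's time series against the design."""
    X = design.X
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"y must have length {n}, got {y.shape}")
    if n <= p:
        raise ValueError(f"need n_scans > p (got n={n}, p={p})")
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular X'X") from exc
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - p
    ss_res = float(resid @ resid)
    if ss_res <= 1e-20 * max(float(y @ y), 1.0):
        ss_res = 0.0  # y lies in the column space up to numerical noise
    sigma2 = ss_res / dof
    return GlmFit(beta=beta, sigma2=sigma2, dof=dof, xtx_inv=xtx_inv,
                  column_names=design.column_names, contrasts=design.contrasts)


def contrast_tstats(fits: list[GlmFit], contrast: str) -> np.ndarray:
    """Per-region t-statistics for a named contrast (e.g. ``"face>shape"``)."""
    if not fits:
        raise ValueError("no fits")
    for fit in fits:
        if contrast not in fit.contrasts:
            raise KeyError(
                f"unknown contrast {contrast!r}; available: {sorted(fit.contrasts)}"
            )
    return np.array([fit.t_stat(contrast) for fit in fits])


def group_ttest(t_values: np.ndarray) -> tuple[float, float]:
    """One-sample t-test against 0 across participants; returns (t, two-sided p)."""
    t_values = np.asarray(t_values, dtype=float)
    if t_values.size < 2:
        raise ValueError("need ≥ 2 values")
    if np.std(t_values, ddof=1) == 0:
        raise ValueError("zero variance across participants")
    res = stats.ttest_1samp(t_values, 0.0)
    return float(res.statistic), float(res.pvalue)
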