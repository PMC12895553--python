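"""rsFCM construction, temporal resampling, normalization, and train/test splitting."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .task_codec import MultimodalSequence

DEFAULT_CLIP_EPS = 1e-7


@dataclass
class RegionTimeSeries:
    """Region × time BOLD table sampled at a uniform interval."""

    values: np.ndarray  # n_regions x n_time
    step_s: float
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D region × time matrix")
        if self.values.shape[0] != len(self.region_labels):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.region_labels)} labels"
            )
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 time points")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite values in time series")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]


@dataclass
class RsFcm:
    """Fisher-z vectorized strictly-upper-triangle of a region correlation matrix."""

    edges: np.ndarray  # length n_regions * (n_regions - 1) / 2
    n_regions: int
    edge_index: list[tuple[int, int]]  # (i, j) with i < j, row-major order

    def __post_init__(self) -> None:
        expected = self.n_regions * (self.n_regions - 1) // 2
        if len(self.edges) != expected:
            raise ValueError(f"expected {expected} edges, got {len(self.edges)}")
        if not np.isfinite(self.edges).all():
            raise ValueError("non-finite edge values")


@dataclass
class NormalizationStats:
    """Per-region mean/SD computed on the training pool."""

    mean: np.ndarray
    sd: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            bad = [self.region_labels[i] for i in np.nonzero(self.sd <= 0)[0]]
            raise ValueError(f"non-positive SD for regions: {bad}")


def edge_index_pairs(n_regions: int) -> list[tuple[int, int]]:
    """Row-major strictly-upper-triangle (i, j) pairs, i < j, 0-based."""
    iu = np.triu_indices(n_regions, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def fisher_z_upper(corr: np.ndarray, clip_eps: float = DEFAULT_CLIP_EPS) -> np.ndarray:
    """Clip correlations to |r| ≤ 1−clip_eps and arctanh the upper triangle."""
    iu = np.triu_indices(corr.shape[0], k=1)
    r = np.clip(corr[iu], -1.0 + clip_eps, 1.0 - clip_eps)
    return np.arctanh(r)


def compute_rsfcm(ts: RegionTimeSeries, clip_eps: float = DEFAULT_CLIP_EPS) -> RsFcm:
    """Pearson correlations between regions, Fisher-z transformed and vectorized."""
    if ts.n_time < 3:
        raise ValueError("need at least 3 time points to correlate")
    sd = ts.values.std(axis=1)
    if np.any(sd == 0):
        bad = [ts.region_labels[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance region(s): {bad}")
    corr = np.corrcoef(ts.values)
    return RsFcm(
        edges=fisher_z_upper(corr, clip_eps),
        n_regions=ts.n_regions,
        edge_index=edge_index_pairs(ts.n_regions),
    )


def resample_series(
    ts: RegionTimeSeries, factor: int, method: str = "cubic"
) -> RegionTimeSeries:
    """Upsample by an integer factor, preserving values at original time points.

    The new grid has (n_time − 1) · factor + 1 points; no extrapolation beyond
    the original endpoints.
    """
    if factor < 1:
        raise ValueError(f"factor must be ≥ 1, got {factor}")
    if factor == 1:
        return RegionTimeSeries(ts.values.copy(), ts.step_s, list(ts.region_labels))
    old_t = np.arange(ts.n_time, dtype=float)
    new_t = np.arange((ts.n_time - 1) * factor + 1, dtype=float) / factor
    if method == "cubic":
        new_values = CubicSpline(old_t, ts.values, axis=1)(new_t)
    elif method == "linear":
        new_values = np.stack([np.interp(new_t, old_t, row) for row in ts.values])
    else:
        raise ValueError(f"method must be 'cubic' or 'linear', got {method!r}")
    # interpolation passes through the knots; enforce exactness at them
    new_values[:, ::factor] = ts.values
    return RegionTimeSeries(new_values, ts.step_s / factor, list(ts.region_labels))


def fit_normalization(train: list[RegionTimeSeries]) -> NormalizationStats:
    """Per-region mean/SD pooled across all training participants and time steps."""
    if not train:
        raise ValueError("empty training pool")
    labels = train[0].region_labels
    for ts in train[1:]:
        if ts.region_labels != labels:
            raise ValueError("inconsistent region labels across training series")
    pooled = np.concatenate([ts.values for ts in train], axis=1)
    mean = pooled.mean(axis=1)
    sd = pooled.std(axis=1)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-SD region(s) in training pool: {bad}")
    return NormalizationStats(mean=mean, sd=sd, region_labels=list(labels))


def apply_normalization(ts: RegionTimeSeries, stats: NormalizationStats) -> RegionTimeSeries:
    if ts.region_labels != stats.region_labels:
        raise ValueError("region labels do not match normalization stats")
    values = (ts.values - stats.mean[:, None]) / stats.sd[:, None]
    return RegionTimeSeries(values, ts.step_s, list(ts.region_labels))


def temporal_split(
    seq: MultimodalSequence, train_duration_s: float
) -> tuple[MultimodalSequence, MultimodalSequence]:
    """Split a sequence into contiguous train/test halves of equal duration.

    Both halves carry absolute time offsets (``t0_s``) so event tables can be
    re-aligned against them.
    """
    if train_duration_s <= 0:
        raise ValueError(f"train_duration_s must be > 0, got {train_duration_s}")
    n_train = int(round(train_duration_s / seq.step_s))
    required = 2 * n_train
    if seq.n_steps < required:
        raise ValueError(
            f"sequence has {seq.n_steps} steps but {required} "
            f"(2 × {train_duration_s} s at {seq.step_s} s) are required"
        )

    def _slice(a: int, b: int) -> MultimodalSequence:
        return MultimodalSequence(
            sensory=seq.sensory[a:b],
            condition=seq.condition[a:b],
            action=seq.action[a:b],
            bold=seq.bold[a:b],
            step_s=seq.step_s,
            t0_s=seq.t0_s + a * seq.step_s,
        )

    return _slice(0, n_train), _slice(n_train, 2 * n_train)


def shift_events(events: pd.DataFrame, t0_s: float, duration_s: float) -> pd.DataFrame:
    """Restrict events to [t0_s, t0_s + duration_s) and rebase onsets to 0."""
    sub = events[(events["onset"] >= t0_s) & (events["onset"] < t0_s + duration_s)].copy()
    for col in ("onset", "cue_onset"):
        if col in sub.columns:
            sub[col] = sub[col] - t0_s
    return sub.reset_index(drop=True)


# -- TSV / JSON round-trips ---------------------------------------------------


def save_region_timeseries(ts: RegionTimeSeries, path: str) -> None:
    """Regions × time TSV; first column is the region label."""
    df = pd.DataFrame(ts.values, index=ts.region_labels)
    df.index.name = "region"
    df.to_csv(path, sep="\t")


def load_region_timeseries(path: str, step_s: float) -> RegionTimeSeries:
    df = pd.read_csv(path, sep="\t", index_col="region")
    return RegionTimeSeries(df.to_numpy(), step_s, list(df.index))


def save_rsfcm(rsfcm: RsFcm, path: str, region_labels: list[str] | None = None) -> None:
    labels = region_labels or [f"r{i}" for i in range(rsfcm.n_regions)]
    pairs = [f"{labels[i]}--{labels[j]}" for i, j in rsfcm.edge_index]
    pd.DataFrame({"edge": pairs, "fisher_z": rsfcm.edges}).to_csv(
        path, sep="\t", index=False
    )


def load_rsfcm(path: str, n_regions: int) -> RsFcm:
    df = pd.read_csv(path, sep="\t")
    return RsFcm(
        edges=df["fisher_z"].to_numpy(),
        n_regions=n_regions,
        edge_index=edge_index_pairs(n_regions),
    )


def save_normalization(stats: NormalizationStats, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "mean": stats.mean.tolist(),
                "sd": stats.sd.tolist(),
                "region_labels": stats.region_labels,
            },
            fh,
            indent=1,
        )


def load_normalization(path: str) -> NormalizationStats:
    with open(path) as fh:
        d = json.load(fh)
    return NormalizationStats(
        mean=np.asarray(d["mean"]), sd=np.asarray(d["sd"]), region_labels=d["region_labels"]
    )
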