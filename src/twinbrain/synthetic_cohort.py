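"""Virtual participants with planted trait → connectome and trait → behavior/BOLD
structure, so every downstream stage is testable without external data.

Each participant carries three kinds of latent traits, drawn i.i.d. standard
normal: an affective trait (controls right-amygdala face-response amplitude),
a cognitive trait (controls response latency and error rate), and nuisance
traits (embedded in the rsFCM but unrelated to behavior). The rsFCM carries a
linear embedding of all traits through a tanh squashing — a synthetic
assumption, chosen as the simplest structure a 2-hidden-layer MLP can learn.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import glm, task_codec
from .preprocess import (
    RegionTimeSeries,
    RsFcm,
    edge_index_pairs,
    fisher_z_upper,
)
from .regions import MODEL_REGIONS_20, RIGHT_AMYGDALA
from .task_codec import EF_TASK, STROOP_TASK, MultimodalSequence

EF_DURATION_S = 394.6
STROOP_DURATION_S = 407.2


@dataclass
class LatentTraits:
    affective: float
    cognitive: float
    nuisance: np.ndarray

    def __post_init__(self) -> None:
        self.nuisance = np.atleast_1d(np.asarray(self.nuisance, dtype=float))
        vals = [self.affective, self.cognitive, *self.nuisance]
        if not np.isfinite(vals).all():
            raise ValueError("traits must be finite")


@dataclass
class ScheduleConfig:
    """Trial timing defaults: cue 2 s, stimulus window 4 s, inter-trial
    interval 6 s, blocked conditions."""

    cue_s: float = 2.0
    stim_s: float = 4.0
    iti_s: float = 6.0
    block_size: int = 4  # trials per condition block

    @property
    def trial_period_s(self) -> float:
        return self.cue_s + self.stim_s + self.iti_s


@dataclass
class BehaviorConfig:
    base_latency_s: float = 0.4
    latency_slope_s: float = 0.16  # seconds per SD of the cognitive trait
    latency_noise_sd_s: float = 0.01  # well under one 0.08-s step: press steps
    # are near-deterministic per participant, which keeps the timing learnable
    error_p0: float = -3.0  # logit of error probability at cognitive = 0
    error_p1: float = 0.5  # logit slope per SD of the cognitive trait


@dataclass
class BoldConfig:
    amygdala_face_a0: float = 1.0
    amygdala_face_a1: float = -0.4  # higher affective trait -> lower amplitude
    base_amplitude_sd: float = 0.5  # per-(region, condition) base amplitudes
    noise_sd: float = 0.2
    ar1_phi: float = 0.3


@dataclass
class EmbedConfig:
    n_nuisance: int = 3
    coef_scale: float = 0.3  # scale of the per-trait edge loading matrices
    base_scale: float = 0.3
    noise_scale: float = 0.02  # participant-specific edge noise E


@dataclass
class CohortConfig:
    n_participants: int = 40
    n_regions: int = 20
    region_labels: list[str] = field(default_factory=lambda: list(MODEL_REGIONS_20))
    tasks: list[str] = field(default_factory=lambda: [EF_TASK, STROOP_TASK])
    ef_duration_s: float = EF_DURATION_S
    stroop_duration_s: float = STROOP_DURATION_S
    step_s: float = task_codec.STEP_S
    press_steps: int = 1  # steps a button press stays active in the action channel
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    bold: BoldConfig = field(default_factory=BoldConfig)
    embed: EmbedConfig = field(default_factory=EmbedConfig)

    def __post_init__(self) -> None:
        if len(self.region_labels) != self.n_regions:
            raise ValueError(
                f"{self.n_regions} regions but {len(self.region_labels)} labels"
            )

    def duration_s(self, task: str) -> float:
        return self.ef_duration_s if task == EF_TASK else self.stroop_duration_s


@dataclass
class Participant:
    traits: LatentTraits
    rsfcm: RsFcm
    events: dict[str, pd.DataFrame]  # per task, responses filled
    sessions: dict[str, MultimodalSequence]  # per task, raw (unnormalized) BOLD


@dataclass
class GroundTruthCohort:
    cfg: CohortConfig
    seed: int
    participants: list[Participant]
    generator_params: dict

    @property
    def n_participants(self) -> int:
        return len(self.participants)


# -- schedule -----------------------------------------------------------------


def generate_schedule(
    task: str,
    duration_s: float,
    step_s: float,
    cfg: ScheduleConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Blocked trial schedule fitting inside ``duration_s``, onsets on the step grid.

    Returned events have no responses yet. ``onset`` is the stimulus onset
    (trials are cue → stimulus window → inter-trial interval).
    """
    if duration_s < 0:
        raise ValueError(f"duration_s must be ≥ 0, got {duration_s}")
    if step_s <= 0:
        raise ValueError(f"step_s must be > 0, got {step_s}")
    cfg = cfg or ScheduleConfig()
    if min(cfg.cue_s, cfg.stim_s) <= 0 or cfg.iti_s < 0:
        raise ValueError(
            "schedule config implies overlapping trials: cue_s and stim_s must be "
            f"> 0 and iti_s ≥ 0 (got cue={cfg.cue_s}, stim={cfg.stim_s}, iti={cfg.iti_s})"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if task == EF_TASK:
        block_conditions = ("face", "shape")
    elif task == STROOP_TASK:
        block_conditions = ("congruent", "incongruent")
    else:
        raise ValueError(f"unknown task {task!r}")

    n_steps = int(np.floor(duration_s / step_s))
    rows = []
    k = 0
    while True:
        trial_start = k * cfg.trial_period_s
        if trial_start + cfg.cue_s + cfg.stim_s > duration_s:
            break
        cue_onset = np.floor(trial_start / step_s) * step_s
        onset = np.floor((trial_start + cfg.cue_s) / step_s) * step_s
        condition = block_conditions[(k // cfg.block_size) % 2]
        row = {
            "onset": onset,
            "duration": cfg.stim_s,
            "trial_type": condition,
            "cue_onset": cue_onset,
            "cue_duration": cfg.cue_s,
        }
        if task == EF_TASK:
            row["correct_response"] = task_codec.EF_CHOICES[rng.integers(2)]
        else:
            ink = task_codec.STROOP_COLORS[rng.integers(3)]
            if condition == "congruent":
                word = ink
            else:
                others = [c for c in task_codec.STROOP_COLORS if c != ink]
                word = others[rng.integers(2)]
            row.update(ink=ink, word=word, correct_response=ink)
        rows.append(row)
        k += 1

    columns = ["onset", "duration", "trial_type", "cue_onset", "cue_duration",
               "correct_response"]
    if task == STROOP_TASK:
        columns += ["ink", "word"]
    events = pd.DataFrame(rows, columns=columns)
    # all onsets sit on the step grid inside the n_steps grid
    assert events.empty or (events["onset"] / step_s).max() < n_steps
    return events


# -- behavior -----------------------------------------------------------------


def simulate_behavior(
    events: pd.DataFrame,
    traits: LatentTraits,
    cfg: BehaviorConfig | None = None,
    seed: int | np.random.Generator = 0,
    step_s: float = task_codec.STEP_S,
) -> pd.DataFrame:
    """Fill response_choice and response latency.

    latency_i = base + slope·cognitive + ε (Gaussian), clipped to
    [1 step, stimulus window − 1 step]; error probability
    p = logistic(p0 + p1·cognitive); the response equals the correct choice
    with probability 1 − p, otherwise uniform over the alternatives.
    """
    cfg = cfg or BehaviorConfig()
    if cfg.base_latency_s < 0:
        raise ValueError(f"negative base_latency_s: {cfg.base_latency_s}")
    if "response" in events.columns and events["response"].notna().any():
        raise ValueError("events already have responses")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = events.copy()
    n = len(out)
    latency = (
        cfg.base_latency_s
        + cfg.latency_slope_s * traits.cognitive
        + rng.normal(0.0, cfg.latency_noise_sd_s, n)
    )
    upper = out["duration"].to_numpy() - step_s if n else step_s
    latency = np.clip(latency, step_s, upper)
    p_err = expit(cfg.error_p0 + cfg.error_p1 * traits.cognitive)
    responses = []
    for i, ev in enumerate(out.itertuples(index=False)):
        choices = task_codec.EF_CHOICES if ev.trial_type in ("face", "shape") \
            else task_codec.STROOP_COLORS
        if rng.random() < p_err:
            alternatives = [c for c in choices if c != ev.correct_response]
            responses.append(alternatives[rng.integers(len(alternatives))])
        else:
            responses.append(ev.correct_response)
    out["response"] = responses
    out["response_time"] = latency
    return out


# -- BOLD ---------------------------------------------------------------------


def _ar1_noise(rng: np.random.Generator, phi: float, sd: float, shape: tuple) -> np.ndarray:
    """AR(1) noise with stationary SD ``sd`` along the last axis."""
    innov_sd = sd * np.sqrt(1.0 - phi ** 2)
    eps = rng.normal(0.0, 1.0, shape)
    noise = np.empty(shape)
    noise[..., 0] = eps[..., 0] * sd
    for t in range(1, shape[-1]):
        noise[..., t] = phi * noise[..., t - 1] + innov_sd * eps[..., t]
    return noise


def condition_amplitudes(
    traits: LatentTraits,
    region_labels: list[str],
    conditions: list[str],
    cfg: BoldConfig,
    base_rng: np.random.Generator,
) -> np.ndarray:
    """Planted (region × condition) response amplitudes.

    Base amplitudes are drawn once per cohort from ``base_rng``; the
    right-amygdala face amplitude is a0 + a1·affective.
    """
    amp = base_rng.normal(0.0, cfg.base_amplitude_sd,
                          (len(region_labels), len(conditions)))
    if RIGHT_AMYGDALA in region_labels and "face" in conditions:
        i = region_labels.index(RIGHT_AMYGDALA)
        j = conditions.index("face")
        amp[i, j] = cfg.amygdala_face_a0 + cfg.amygdala_face_a1 * traits.affective
    return amp


def simulate_bold(
    events: pd.DataFrame,
    traits: LatentTraits,
    region_labels: list[str],
    cfg: BoldConfig | None = None,
    seed: int | np.random.Generator = 0,
    duration_s: float = EF_DURATION_S,
    step_s: float = task_codec.STEP_S,
    base_rng: np.random.Generator | None = None,
) -> RegionTimeSeries:
    """HRF-convolved region-wise BOLD: Σ_conditions amplitude · (boxcar ⊛ HRF)
    plus AR(1) noise."""
    cfg = cfg or BoldConfig()
    if RIGHT_AMYGDALA not in region_labels:
        raise ValueError(f"region list must include {RIGHT_AMYGDALA!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if base_rng is None:
        base_rng = np.random.default_rng(0)
    n_steps = int(np.floor(duration_s / step_s))
    conditions = list(dict.fromkeys(events["trial_type"])) if len(events) else []
    amp = condition_amplitudes(traits, region_labels, conditions, cfg, base_rng)

    kernel = glm.glover_hrf(np.arange(0.0, glm.HRF_LENGTH_S + step_s / 2, step_s))
    signal = np.zeros((len(region_labels), n_steps))
    for j, cond in enumerate(conditions):
        box = glm.condition_boxcar(events, cond, n_steps, step_s)
        reg = np.convolve(box, kernel)[:n_steps]
        signal += amp[:, j:j + 1] * reg[None, :]
    if cfg.noise_sd > 0:
        signal = signal + _ar1_noise(rng, cfg.ar1_phi, cfg.noise_sd,
                                     (len(region_labels), n_steps))
    return RegionTimeSeries(signal, step_s, list(region_labels))


# -- rsFCM embedding ----------------------------------------------------------


def _symmetric_loading(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    B = rng.normal(0.0, scale, (n, n))
    B = (B + B.T) / 2.0
    np.fill_diagonal(B, 0.0)
    return B


def make_embedding_basis(
    n_regions: int, cfg: EmbedConfig, seed: int | np.random.Generator = 0
) -> dict[str, np.ndarray]:
    """Fixed-per-cohort loading matrices B0, B_affective, B_cognitive, B_nuisance."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return {
        "B0": _symmetric_loading(rng, n_regions, cfg.base_scale),
        "B_affective": _symmetric_loading(rng, n_regions, cfg.coef_scale),
        "B_cognitive": _symmetric_loading(rng, n_regions, cfg.coef_scale),
        "B_nuisance": np.stack(
            [_symmetric_loading(rng, n_regions, cfg.coef_scale)
             for _ in range(cfg.n_nuisance)]
        ),
    }


def embed_rsfcm(
    traits: LatentTraits,
    n_regions: int,
    cfg: EmbedConfig | None = None,
    basis: dict[str, np.ndarray] | None = None,
    seed: int | np.random.Generator = 0,
) -> RsFcm:
    """Symmetric M = tanh(B0 + affective·B_a + cognitive·B_c + Σ nuisance·B_k + E),
    diagonal 1, returned as the Fisher-z upper-triangle vector."""
    if n_regions < 2:
        raise ValueError(f"n_regions must be ≥ 2, got {n_regions}")
    cfg = cfg or EmbedConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if basis is None:
        basis = make_embedding_basis(n_regions, cfg, rng)
    if len(traits.nuisance) != basis["B_nuisance"].shape[0]:
        raise ValueError("nuisance trait count does not match embedding basis")
    pre = (
        basis["B0"]
        + traits.affective * basis["B_affective"]
        + traits.cognitive * basis["B_cognitive"]
        + np.einsum("k,kij->ij", traits.nuisance, basis["B_nuisance"])
    )
    if cfg.noise_scale > 0:
        pre = pre + _symmetric_loading(rng, n_regions, cfg.noise_scale)
    M = np.tanh(pre)
    np.fill_diagonal(M, 1.0)
    return RsFcm(
        edges=fisher_z_upper(M),
        n_regions=n_regions,
        edge_index=edge_index_pairs(n_regions),
    )


# -- cohort assembly ----------------------------------------------------------


def generate_cohort(cfg: CohortConfig | None = None, seed: int = 0) -> GroundTruthCohort:
    """Generate a full cohort: traits, rsFCMs, event tables with responses,
    and raw multimodal sessions per task. Fully deterministic under ``seed``."""
    cfg = cfg or CohortConfig()
    root = np.random.default_rng(seed)
    basis_seed = int(root.integers(2 ** 31))
    amp_seed = int(root.integers(2 ** 31))
    participant_seeds = [int(root.integers(2 ** 31)) for _ in range(cfg.n_participants)]
    basis = make_embedding_basis(cfg.n_regions, cfg.embed, basis_seed)

    participants = []
    for i in range(cfg.n_participants):
        p_rng = np.random.default_rng(participant_seeds[i])
        traits = LatentTraits(
            affective=p_rng.standard_normal(),
            cognitive=p_rng.standard_normal(),
            nuisance=p_rng.standard_normal(cfg.embed.n_nuisance),
        )
        rsfcm = embed_rsfcm(traits, cfg.n_regions, cfg.embed, basis, p_rng)
        events_by_task, sessions = {}, {}
        for task in cfg.tasks:
            duration = cfg.duration_s(task)
            schedule = generate_schedule(task, duration, cfg.step_s, cfg.schedule, p_rng)
            events = simulate_behavior(schedule, traits, cfg.behavior, p_rng, cfg.step_s)
            # planted base amplitudes are shared across the cohort (fixed seed)
            bold_ts = simulate_bold(
                events, traits, cfg.region_labels, cfg.bold, p_rng,
                duration_s=duration, step_s=cfg.step_s,
                base_rng=np.random.default_rng(amp_seed),
            )
            seq = task_codec.build_sequence(
                task, events, bold_ts.values.T, cfg.step_s, 0.0, p_rng,
                cfg.press_steps,
            )
            events_by_task[task] = events
            sessions[task] = seq
        participants.append(Participant(traits, rsfcm, events_by_task, sessions))

    generator_params = {
        "seed": seed,
        "basis_seed": basis_seed,
        "amp_seed": amp_seed,
        "participant_seeds": participant_seeds,
        "amygdala_face_amplitude_sign": float(np.sign(cfg.bold.amygdala_face_a1)),
        "press_steps": cfg.press_steps,
        "latency_clip": "[1 step, stimulus window - 1 step]",
        "schedule": asdict(cfg.schedule),
        "behavior": asdict(cfg.behavior),
        "bold": asdict(cfg.bold),
        "embed": asdict(cfg.embed),
    }
    return GroundTruthCohort(cfg, seed, participants, generator_params)


def write_cohort(cohort: GroundTruthCohort, out_dir: str) -> None:
    """One directory per participant: rsfcm.tsv, {task}_events.tsv, {task}_bold.tsv,
    plus a cohort-level cohort.json with generator params."""
    os.makedirs(out_dir, exist_ok=True)
    cfg = cohort.cfg
    meta = {
        "n_participants": cohort.n_participants,
        "n_regions": cfg.n_regions,
        "region_labels": cfg.region_labels,
        "tasks": cfg.tasks,
        "step_s": cfg.step_s,
        "traits": [
            {"affective": p.traits.affective, "cognitive": p.traits.cognitive,
             "nuisance": p.traits.nuisance.tolist()}
            for p in cohort.participants
        ],
        "generator_params": cohort.generator_params,
    }
    with open(os.path.join(out_dir, "cohort.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    for i, p in enumerate(cohort.participants):
        pdir = os.path.join(out_dir, f"sub-{i:03d}")
        os.makedirs(pdir, exist_ok=True)
        pairs = [f"{cfg.region_labels[a]}--{cfg.region_labels[b]}"
                 for a, b in p.rsfcm.edge_index]
        pd.DataFrame({"edge": pairs, "fisher_z": p.rsfcm.edges}).to_csv(
            os.path.join(pdir, "rsfcm.tsv"), sep="\t", index=False
        )
        for task in cfg.tasks:
            p.events[task].to_csv(
                os.path.join(pdir, f"{task}_events.tsv"), sep="\t", index=False
            )
            bold = pd.DataFrame(p.sessions[task].bold.T, index=cfg.region_labels)
            bold.index.name = "region"
            bold.to_csv(os.path.join(pdir, f"{task}_bold.tsv"), sep="\t")
            seq = p.sessions[task]
            chans = pd.DataFrame(
                np.concatenate([seq.sensory, seq.condition, seq.action], axis=1),
                columns=[f"sensory_{d}" for d in range(seq.sensory.shape[1])]
                + ["condition"]
                + [f"action_{d}" for d in range(seq.action.shape[1])],
            )
            chans.to_csv(os.path.join(pdir, f"{task}_channels.tsv"), sep="\t",
                         index=False)


def load_cohort(in_dir: str) -> GroundTruthCohort:
    """Reload a cohort written by :func:`write_cohort` (bit-exact channels)."""
    with open(os.path.join(in_dir, "cohort.json")) as fh:
        meta = json.load(fh)
    gp = meta["generator_params"]
    cfg = CohortConfig(
        n_participants=meta["n_participants"],
        n_regions=meta["n_regions"],
        region_labels=meta["region_labels"],
        tasks=meta["tasks"],
        step_s=meta["step_s"],
        press_steps=gp.get("press_steps", 1),
        schedule=ScheduleConfig(**gp["schedule"]),
        behavior=BehaviorConfig(**gp["behavior"]),
        bold=BoldConfig(**gp["bold"]),
        embed=EmbedConfig(**gp["embed"]),
    )
    participants = []
    for i, tr in enumerate(meta["traits"]):
        pdir = os.path.join(in_dir, f"sub-{i:03d}")
        traits = LatentTraits(tr["affective"], tr["cognitive"], np.asarray(tr["nuisance"]))
        edges = pd.read_csv(os.path.join(pdir, "rsfcm.tsv"), sep="\t")["fisher_z"]
        rsfcm = RsFcm(edges.to_numpy(), cfg.n_regions, edge_index_pairs(cfg.n_regions))
        events_by_task, sessions = {}, {}
        for task in cfg.tasks:
            events = pd.read_csv(os.path.join(pdir, f"{task}_events.tsv"), sep="\t")
            bold = pd.read_csv(
                os.path.join(pdir, f"{task}_bold.tsv"), sep="\t", index_col="region"
            ).to_numpy().T
            chans = pd.read_csv(os.path.join(pdir, f"{task}_channels.tsv"), sep="\t")
            n_sens = sum(c.startswith("sensory_") for c in chans.columns)
            sessions[task] = MultimodalSequence(
                sensory=chans.iloc[:, :n_sens].to_numpy(),
                condition=chans[["condition"]].to_numpy(),
                action=chans.filter(like="action_").to_numpy(),
                bold=bold,
                step_s=cfg.step_s,
            )
            events_by_task[task] = events
        participants.append(Participant(traits, rsfcm, events_by_task, sessions))
    return GroundTruthCohort(cfg, gp["seed"], participants, gp)
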