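"""Encoding of trial events into model channels, and decoding of model outputs.

Channel layout (fixed by design, the roles come from the task structure):

Emotional Faces sensory (8 dims)
    0–1  cue indicators ("match faces" / "match shapes"), 1 during cue else 0
    2–3  target stimulus (top of screen), 2 dims
    4–5  left probe, 2 dims
    6–7  right probe, 2 dims
    Face stimuli are 2-bit identity patterns rendered with values drawn from
    U[0, 0.1] (bit 0) or U[0.9, 1] (bit 1); the matching probe duplicates the
    target's rendered pattern. Shape stimuli are exact {0, 1} orientation codes.

Stroop sensory (8 dims)
    0–2  ink color one-hot (red, green, blue)
    3–5  word identity one-hot (red, green, blue)
    6–7  always 0

Task-condition channel: constant 0 (Emotional Faces) or 1 (Stroop).

Action (3 dims): Emotional Faces uses dims 0 (left) and 1 (right), dim 2 is
always 0; Stroop uses one dim per color button (red, green, blue). A press is
rendered as ``press_steps`` consecutive active steps (default one 80-ms step);
decoding always uses the first threshold crossing, so the press duration never
affects decoded reaction times or choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STEP_S = 0.08
STEP_MS = 80.0

N_SENSORY = 8
N_ACTION = 3

EF_TASK = "emotional_faces"
STROOP_TASK = "stroop"

EF_CHOICES = ("left", "right")
STROOP_COLORS = ("red", "green", "blue")

# 2-bit identity patterns cycled over stimuli.
FACE_PATTERNS = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass
class MultimodalSequence:
    """Aligned per-time-step channels at ``step_s`` resolution."""

    sensory: np.ndarray  # T x 8, values in [0, 1]
    condition: np.ndarray  # T x 1, constant 0/1
    action: np.ndarray  # T x 3, values in [0, 1]
    bold: np.ndarray  # T x n_regions
    step_s: float = STEP_S
    t0_s: float = 0.0  # absolute time of the first step

    def __post_init__(self) -> None:
        lengths = {
            self.sensory.shape[0],
            self.condition.shape[0],
            self.action.shape[0],
            self.bold.shape[0],
        }
        if len(lengths) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")

    @property
    def n_steps(self) -> int:
        return self.sensory.shape[0]

    def inputs(self) -> np.ndarray:
        """Concatenated sensory + task-condition input, T x 9."""
        return np.concatenate([self.sensory, self.condition], axis=1)


def _onset_step(onset_s: float, step_s: float) -> int:
    # events align to the grid by flooring
    return int(np.floor(onset_s / step_s + 1e-9))


def _render_face_bits(bits: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    vals = np.empty(2)
    for d, b in enumerate(bits):
        vals[d] = rng.uniform(0.9, 1.0) if b else rng.uniform(0.0, 0.1)
    return vals


def encode_emotional_faces(
    events: pd.DataFrame,
    n_steps: int,
    step_s: float = STEP_S,
    seed: int | np.random.Generator = 0,
    press_steps: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode Emotional Faces trial events into (sensory T×8, action T×3).

    ``events`` columns: onset (stimulus onset, s), duration, trial_type in
    {face, shape}, cue_onset, cue_duration, correct_response in {left, right},
    and optionally response / response_time (s, latency from onset).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sensory = np.zeros((n_steps, N_SENSORY))
    action = np.zeros((n_steps, N_ACTION))

    for k, ev in enumerate(events.itertuples(index=False)):
        ttype = ev.trial_type
        if ttype not in ("face", "shape"):
            raise ValueError(f"unknown Emotional Faces condition {ttype!r}")
        cue_dim = 0 if ttype == "face" else 1
        c0 = _onset_step(ev.cue_onset, step_s)
        c1 = _onset_step(ev.cue_onset + ev.cue_duration, step_s)
        sensory[c0:min(c1, n_steps), cue_dim] = 1.0

        s0 = _onset_step(ev.onset, step_s)
        s1 = min(_onset_step(ev.onset + ev.duration, step_s), n_steps)
        if s0 >= n_steps:
            continue

        target_bits = FACE_PATTERNS[k % len(FACE_PATTERNS)]
        foil_bits = FACE_PATTERNS[(k + 1) % len(FACE_PATTERNS)]
        if ttype == "face":
            target_vals = _render_face_bits(target_bits, rng)
            foil_vals = _render_face_bits(foil_bits, rng)
        else:
            target_vals = np.asarray(target_bits, dtype=float)
            foil_vals = np.asarray(foil_bits, dtype=float)
        # matching probe duplicates the target's rendered pattern
        if ev.correct_response == "left":
            left_vals, right_vals = target_vals, foil_vals
        elif ev.correct_response == "right":
            left_vals, right_vals = foil_vals, target_vals
        else:
            raise ValueError(
                f"Emotional Faces correct_response must be left/right, "
                f"got {ev.correct_response!r}"
            )
        sensory[s0:s1, 2:4] = target_vals
        sensory[s0:s1, 4:6] = left_vals
        sensory[s0:s1, 6:8] = right_vals

        response = getattr(ev, "response", None)
        if response is None or (isinstance(response, float) and np.isnan(response)):
            continue
        if response not in EF_CHOICES:
            raise ValueError(
                f"Emotional Faces uses 2 buttons {EF_CHOICES}, got {response!r}"
            )
        r_step = _onset_step(ev.onset + ev.response_time, step_s)
        if r_step < n_steps:
            action[r_step:r_step + press_steps, EF_CHOICES.index(response)] = 1.0
    return sensory, action


def encode_stroop(
    events: pd.DataFrame, n_steps: int, step_s: float = STEP_S,
    press_steps: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode Stroop trial events into (sensory T×8, action T×3).

    ``events`` columns: onset, duration, trial_type in {congruent,
    incongruent}, ink, word (colors), and optionally response / response_time.
    Dims 6–7 of the sensory input stay 0 throughout.
    """
    sensory = np.zeros((n_steps, N_SENSORY))
    action = np.zeros((n_steps, N_ACTION))
    for ev in events.itertuples(index=False):
        if ev.trial_type not in ("congruent", "incongruent"):
            raise ValueError(f"unknown Stroop condition {ev.trial_type!r}")
        for col, offset in ((ev.ink, 0), (ev.word, 3)):
            if col not in STROOP_COLORS:
                raise ValueError(f"unknown color {col!r}; expected one of {STROOP_COLORS}")
        if (ev.trial_type == "congruent") != (ev.ink == ev.word):
            raise ValueError(
                f"trial_type {ev.trial_type!r} inconsistent with ink={ev.ink!r} "
                f"word={ev.word!r}"
            )
        s0 = _onset_step(ev.onset, step_s)
        s1 = min(_onset_step(ev.onset + ev.duration, step_s), n_steps)
        if s0 >= n_steps:
            continue
        sensory[s0:s1, STROOP_COLORS.index(ev.ink)] = 1.0
        sensory[s0:s1, 3 + STROOP_COLORS.index(ev.word)] = 1.0

        response = getattr(ev, "response", None)
        if response is None or (isinstance(response, float) and np.isnan(response)):
            continue
        if response not in STROOP_COLORS:
            raise ValueError(f"unknown color {response!r}; expected one of {STROOP_COLORS}")
        r_step = _onset_step(ev.onset + ev.response_time, step_s)
        if r_step < n_steps:
            action[r_step:r_step + press_steps, STROOP_COLORS.index(response)] = 1.0
    return sensory, action


def encode_task_condition(task: str, n_steps: int) -> np.ndarray:
    """Constant task-condition channel: 0 for Emotional Faces, 1 for Stroop."""
    if task == EF_TASK:
        value = 0.0
    elif task == STROOP_TASK:
        value = 1.0
    else:
        raise ValueError(f"unknown task {task!r}")
    return np.full((n_steps, 1), value)


def task_choice_labels(task: str) -> tuple[str, ...]:
    if task == EF_TASK:
        return EF_CHOICES
    if task == STROOP_TASK:
        return STROOP_COLORS
    raise ValueError(f"unknown task {task!r}")


def _trial_windows(events: pd.DataFrame, n_steps: int, step_s: float) -> list[tuple[int, int]]:
    onsets = [_onset_step(o, step_s) for o in events["onset"]]
    windows = []
    for i, s0 in enumerate(onsets):
        s1 = onsets[i + 1] if i + 1 < len(onsets) else n_steps
        windows.append((min(s0, n_steps), min(s1, n_steps)))
    return windows


def decode_choices(
    pred_action: np.ndarray,
    events: pd.DataFrame,
    task: str,
    threshold: float = 0.5,
    step_s: float = STEP_S,
) -> list[str | None]:
    """Per-trial predicted choice from an action-probability time series.

    Within each trial's window [onset, next onset) the predicted choice is the
    argmax over dims of the per-dim peak activation, counted only if that peak
    reaches ``threshold``; ties break toward the lowest dim index.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    labels = task_choice_labels(task)
    choices: list[str | None] = []
    for s0, s1 in _trial_windows(events, pred_action.shape[0], step_s):
        window = pred_action[s0:s1, : len(labels)]
        if window.size == 0:
            choices.append(None)
            continue
        peaks = window.max(axis=0)
        best = int(np.argmax(peaks))  # argmax returns the first (lowest) index on ties
        choices.append(labels[best] if peaks[best] >= threshold else None)
    return choices


def extract_reaction_times(
    pred_action: np.ndarray,
    events: pd.DataFrame,
    threshold: float = 0.5,
    step_s: float = STEP_S,
) -> tuple[np.ndarray, int]:
    """Per-trial RTs in ms from the first threshold crossing after stimulus onset.

    RT = (first step in the trial window where any action dim ≥ threshold −
    stimulus-onset step) × 80 ms. Trials with no crossing are excluded;
    the second return value counts them.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    step_ms = step_s * 1000.0
    rts = []
    excluded = 0
    for s0, s1 in _trial_windows(events, pred_action.shape[0], step_s):
        window = pred_action[s0:s1]
        hits = np.nonzero((window >= threshold).any(axis=1))[0]
        if hits.size == 0:
            excluded += 1
        else:
            rts.append(hits[0] * step_ms)
    return np.asarray(rts, dtype=float), excluded


def concordance_rate(
    pred_choices: list[str | None], observed_choices: list[str | None]
) -> float:
    """Fraction of trials whose predicted choice matches the observed one.

    Trials with no predicted press count as mismatches.
    """
    if len(pred_choices) != len(observed_choices):
        raise ValueError(
            f"trial counts differ: {len(pred_choices)} vs {len(observed_choices)}"
        )
    if not pred_choices:
        raise ValueError("no trials")
    matches = sum(
        1 for p, o in zip(pred_choices, observed_choices) if p is not None and p == o
    )
    return matches / len(pred_choices)


def build_sequence(
    task: str,
    events: pd.DataFrame,
    bold: np.ndarray,
    step_s: float = STEP_S,
    t0_s: float = 0.0,
    seed: int | np.random.Generator = 0,
    press_steps: int = 1,
) -> MultimodalSequence:
    """Assemble a MultimodalSequence from events and a (T × n_regions) BOLD table.

    ``press_steps`` controls how many consecutive steps a button press
    activates (default a single 80-ms step); RT decoding uses the first
    crossing, so widening a press never changes decoded reaction times.
    """
    n_steps = bold.shape[0]
    if task == EF_TASK:
        sensory, action = encode_emotional_faces(events, n_steps, step_s, seed,
                                                 press_steps)
    elif task == STROOP_TASK:
        sensory, action = encode_stroop(events, n_steps, step_s, press_steps)
    else:
        raise ValueError(f"unknown task {task!r}")
    condition = encode_task_condition(task, n_steps)
    return MultimodalSequence(sensory, condition, action, bold, step_s, t0_s)
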