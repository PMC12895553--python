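import numpy as np
import pandas as pd
import pytest

from twinbrain import synthetic_cohort as sc
from twinbrain.task_codec import EF_TASK


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def tiny_cohort_config(n_participants=5, tasks=(EF_TASK,), duration=98.0):
    return sc.CohortConfig(
        n_participants=n_participants,
        n_regions=20,
        tasks=list(tasks),
        ef_duration_s=duration,
        stroop_duration_s=duration,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """5-participant Emotional-Faces-only cohort for cheap integration tests."""
    return sc.generate_cohort(tiny_cohort_config(), seed=11)


@pytest.fixture(scope="session")
def toy_trained():
    """The full toy twin (40 participants, 32/32) trained once per session.

    This is the expensive fixture backing the stochastic acceptance criteria;
    it takes a few minutes on one CPU.
    """
    from twinbrain import presets

    cohort, splits, hp, model_cfg, log = presets.train_toy_twin(seed=7)
    return {
        "cohort": cohort,
        "splits": splits,
        "hp": hp,
        "model_cfg": model_cfg,
        "log": log,
    }


def ef_events_frame(rows):
    """Build an Emotional Faces events table from (onset, duration, trial_type,
    cue_onset, cue_duration, correct_response[, response, response_time]) dicts."""
    return pd.DataFrame(rows)
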