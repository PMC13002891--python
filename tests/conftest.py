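import numpy as np
import pytest

from pupiltrace.data_model import SampleTrack, TrialEvent
from pupiltrace.synth import SynthConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(diameter, rate_hz=500.0, valid=None, pid="p1", task="recognition"):
    diameter = np.asarray(diameter, dtype=float)
    n = len(diameter)
    if valid is None:
        valid = np.isfinite(diameter)
    return SampleTrack(
        participant_id=pid,
        task=task,
        rate_hz=rate_hz,
        time_s=np.arange(n) / rate_hz,
        diameter_mm=diameter,
        valid=np.asarray(valid, dtype=bool),
    )


def make_event(trial_id=0, fixation=0.0, rt=1.5, condition="weak",
               task="recognition", response="old", correct=True, pid="p1"):
    return TrialEvent(
        trial_id=trial_id,
        participant_id=pid,
        task=task,
        condition=condition,
        fixation_onset_s=fixation,
        stimulus_onset_s=fixation + 3.0,
        rt_s=rt,
        response=response,
        correct=correct,
    )


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic cued-recall study (8 participants)."""
    cfg = SynthConfig(n_participants=8, task="cued_recall", n_weak=12,
                      n_strong=8, seed=42,
                      acc_prob={"cued_recall": {"weak": 0.6, "strong": 0.7},
                                "recognition": {"weak": 0.72, "strong": 0.87,
                                                "foil": 0.885}})
    return generate_study(cfg)
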