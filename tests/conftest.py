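import numpy as np
import pytest

from pfcplast.dataset import TrialRecord
from pfcplast.synthgen import SynthConfig, generate_experiment


def make_passive_trial(trial_id=0, cue=0, match=True, phase="pre",
                       delay=1.5, fixation=1.0, cue_s=0.5, sample_s=0.5):
    """A hand-built passive trial with explicit event times."""
    from pfcplast.dataset import diametric_location
    sample = cue if match else diametric_location(cue)
    if cue == 4 and not match:
        sample = 1
    cue_on = fixation
    cue_off = cue_on + cue_s
    sample_on = cue_off + delay
    sample_off = sample_on + sample_s
    return TrialRecord(
        trial_id=trial_id, task="passive", phase=phase,
        cue_location=cue, sample_location=sample,
        is_match=(cue == sample), correct=True,
        fixation_on=0.0, cue_on=cue_on, cue_off=cue_off,
        sample_on=sample_on, sample_off=sample_off,
        targets_on=float("nan"), end=sample_off + delay,
    )


def make_active_trial(trial_id=0, cue=5, match=True, phase="III",
                      delay=0.25, fixation=1.0, cue_s=0.5, sample_s=0.5):
    from pfcplast.dataset import diametric_location
    sample = cue if match else diametric_location(cue)
    cue_on = fixation
    cue_off = cue_on + cue_s
    sample_on = cue_off + delay
    sample_off = sample_on + sample_s
    targets_on = sample_off + delay
    return TrialRecord(
        trial_id=trial_id, task="active", phase=phase,
        cue_location=cue, sample_location=sample,
        is_match=(cue == sample), correct=True,
        fixation_on=0.0, cue_on=cue_on, cue_off=cue_off,
        sample_on=sample_on, sample_off=sample_off,
        targets_on=targets_on, end=targets_on + 0.5,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-phase synthetic experiment shared across tests."""
    cfg = SynthConfig(
        n_units=24, n_trials_per_condition=3, sessions_per_phase=1,
        n_lfp_electrodes=4, seed=20250925, phases=("pre", "III"),
    )
    return generate_experiment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
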