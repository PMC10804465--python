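import numpy as np
import pytest

import sonorsa as s

#: raw 32x32 synthetic imagery downsampled to 16x16 keeps the whole suite fast
SMALL_RAW = (32, 32)
SMALL_TARGET = (16, 16)


@pytest.fixture(scope="session")
def small_config() -> s.RunConfig:
    return s.RunConfig(downsample_to=SMALL_TARGET)


@pytest.fixture(scope="session")
def small_gt() -> s.SyntheticGroundTruth:
    return s.default_ground_truth(seed=7, raw_size=SMALL_RAW)


@pytest.fixture(scope="session")
def paired_subject(small_gt):
    """One synthetic subject: (affected TrialSet, unaffected TrialSet, gt)."""
    return s.generate_subject(small_gt, seed=11)


@pytest.fixture(scope="session")
def affected_states(paired_subject, small_config):
    """End muscle states of the affected limb after the standard pipeline."""
    aff, _, _ = paired_subject
    down, mask = s.preprocess_limb(aff, small_config)
    return s.end_state_set(down, mask), mask


def make_state_set(rng, n_per_class=5, n_features=30, classes=s.MOVEMENTS,
                   separation=4.0, noise=1.0, limb="affected"):
    """Separable random muscle states: one prototype per class plus noise."""
    protos = {m: rng.normal(0, separation, size=n_features) for m in classes}
    states, labels = [], []
    for m in classes:
        for t in range(1, n_per_class + 1):
            vec = protos[m] + rng.normal(0, noise, size=n_features)
            states.append(
                s.MuscleState(values=vec, source="end", subject_id="fx",
                              limb=limb, movement=m, trial_index=t)
            )
            labels.append(m)
    return s.LabeledStateSet(states=states, labels=labels, subject_id="fx", limb=limb)
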