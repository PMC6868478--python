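import numpy as np
import pytest

from cogload.features import extract_features
from cogload.preprocess import Recording, hampel_filter, segment_trials, to_bipolar
from cogload.simulate import SessionSpec, generate_session


def session_features(seed, hampel=False, **spec_overrides):
    """Generate one session and run it through the preprocessing chain.

    Property-style experiments default to impulse-free sessions with the
    Hampel stage disabled (a near-no-op without impulses) to keep many-seed
    runs fast; pass ``hampel=True`` with impulses for the full chain.
    """
    overrides = {"impulse_rate": 0.0}
    overrides.update(spec_overrides)
    spec = SessionSpec(seed=seed, **overrides)
    recording, trace, sequences = generate_session(spec)
    if hampel:
        cleaned = np.stack([hampel_filter(ch, sampling_rate=recording.sampling_rate)
                            for ch in recording.samples])
        recording = Recording(cleaned, recording.sampling_rate,
                              recording.channel_labels, recording.markers)
    trials = segment_trials(to_bipolar(recording), duration=spec.trial_duration)
    features = extract_features(trials, participant_id=spec.participant_id)
    return features, trace, sequences


@pytest.fixture(scope="session")
def default_session():
    """One full default session (impulses included), generated once."""
    spec = SessionSpec(participant_id="P07", seed=7)
    return generate_session(spec)


@pytest.fixture(scope="session")
def default_features(default_session):
    """Features from the default session via the full chain incl. Hampel."""
    recording, _, _ = default_session
    cleaned = np.stack([hampel_filter(ch, sampling_rate=recording.sampling_rate)
                        for ch in recording.samples])
    rec = Recording(cleaned, recording.sampling_rate,
                    recording.channel_labels, recording.markers)
    trials = segment_trials(to_bipolar(rec))
    return extract_features(trials, participant_id="P07")
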