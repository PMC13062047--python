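import numpy as np
import pytest

import somnotherm as st


@pytest.fixture(scope="session")
def wt_session():
    """One clean 1-hour WT session at room temperature."""
    preset = st.make_preset("WT")
    spec = st.SessionSpec("wt1", preset, 3600.0, 250.0, [("RT", 3600.0)], seed=5)
    return st.generate_session(spec)


@pytest.fixture(scope="session")
def ds_session():
    """One clean 1-hour DS session (no NREM delta surge, spikes present)."""
    preset = st.make_preset("DS")
    spec = st.SessionSpec("ds1", preset, 3600.0, 250.0, [("RT", 3600.0)], seed=7)
    return st.generate_session(spec)


@pytest.fixture(scope="session")
def wt_features(wt_session):
    from somnotherm.vigilance import compute_epoch_features

    return compute_epoch_features(wt_session.recording)


def make_recording(channels, fs=250.0, subject_id="t"):
    return st.SignalRecording([(l, np.asarray(x, float)) for l, x in channels],
                              fs, subject_id)
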