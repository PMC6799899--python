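import numpy as np
import pandas as pd
import pytest

from gistate.io import Channel, Event, SessionRecording
from gistate.io import Segment as SegmentRecord
from gistate.synth import SynthConfig, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_session(
    samples: np.ndarray,
    fs: float = 250.0,
    n_paddles: int = 2,
    events: list[Event] | None = None,
    session_id: str = "test",
) -> SessionRecording:
    """Wrap a [n_samples, n_paddles*4] matrix as a session with 4-contact paddles."""
    channels = []
    for p in range(n_paddles):
        pid = "ABCDEF"[p]
        for c in range(4):
            channels.append(Channel(f"{pid}{c + 1}", pid, c + 1))
    return SessionRecording(
        session_id=session_id,
        fs_native=fs,
        channels=channels,
        samples=samples,
        events=events or [],
    )


def make_segment(
    samples: np.ndarray, fs: float = 10.0, source_id: str = "paddle:A", index: int = 0
) -> SegmentRecord:
    return SegmentRecord(
        source_id=source_id, index=index, start_s=index * 60.0, fs=fs, samples=samples
    )


def tone_segment(freq_cpm: float, amplitude: float = 1.0, fs: float = 10.0,
                 phase: float = 0.0) -> SegmentRecord:
    """A 60 s pure sinusoid segment at the analysis rate."""
    t = np.arange(int(60 * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq_cpm / 60.0 * t + phase)
    return make_segment(x, fs=fs)


@pytest.fixture(scope="session")
def default_session():
    """One default synthetic emetine session (shared; treat as read-only)."""
    return generate_session(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def labeled_features(default_session):
    """Median-normalized, state-labeled feature table for the default session."""
    from gistate.features import extract_features, median_normalize
    from gistate.labeling import assign_state_labels
    from gistate.preprocess import preprocess_session

    traces = preprocess_session(default_session)
    table = pd.concat([extract_features(tr) for tr in traces], ignore_index=True)
    table = median_normalize(table)
    return assign_state_labels(table, default_session.events)
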