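import numpy as np
import pytest

from ncl_eeg.pipeline import PipelineConfig, compute_features
from ncl_eeg.synthdata import SynthConfig, generate_session


@pytest.fixture(scope="session")
def default_session():
    """Default synthetic session: 8 alternating 30-s state blocks."""
    cfg = SynthConfig(seed=11)
    rec, labels = generate_session(cfg)
    return cfg, rec, labels


@pytest.fixture(scope="session")
def default_features(default_session):
    """Feature matrix + aligned ground-truth states for the default session."""
    _, rec, labels = default_session
    pcfg = PipelineConfig(seed=11)
    fm, times = compute_features(rec, pcfg)
    states = np.array(labels.states)[fm.segment_index]
    return fm, states, pcfg


@pytest.fixture
def rng():
    return np.random.default_rng(42)
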