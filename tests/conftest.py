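import numpy as np
import pytest
from hypothesis import settings

import engage_fuse as ef

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_session():
    """A short two-participant recording for labeling/feature tests."""
    cfg = ef.SimulationConfig(n_participants=2, n_trials=12, seed=7)
    return ef.generate_sessions(cfg)[0]


@pytest.fixture(scope="session")
def small_labels(small_session):
    return ef.label_session(small_session)


@pytest.fixture(scope="session")
def small_table(small_session, small_labels):
    return ef.extract_features(small_session, small_labels, "hybrid")


def _corpus(cfg):
    sessions = ef.generate_sessions(cfg)
    labels = [ef.label_session(s) for s in sessions]
    agree, total = 0, 0
    for s, lab in zip(sessions, labels):
        kept = lab[lab["label"] != "unlabeled"]
        agree += int((kept["label"].to_numpy() == s.latent_states[kept["window_id"]]).sum())
        total += len(kept)
    table = ef.build_feature_table(sessions, labels)
    return dict(sessions=sessions, table=table, label_agreement=agree / total)


@pytest.fixture(scope="session")
def separable_corpus():
    """Strongly separated default profiles; 11 participants, ~1000 windows."""
    return _corpus(ef.SimulationConfig(n_participants=11, n_trials=95, seed=0))


@pytest.fixture(scope="session")
def null_corpus():
    """Identical state profiles: the no-signal calibration corpus."""
    return _corpus(ef.null_config(n_participants=11, n_trials=60, seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
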