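import numpy as np
import pytest

from ecogstate import (
    ClusterConfig,
    SynthConfig,
    generate,
    ground_truth_labels,
)
from ecogstate.pipeline import RunConfig, extract_features, run
from ecogstate.preprocess import bandpass, window
from ecogstate.synthetic import alternating_schedule


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_fixture():
    """2 files x 2 min, 8 channels, alternating 60-s planted states."""
    cfg = SynthConfig(n_channels=8, fs=500.0, file_length_s=120.0, n_files=2, seed=1)
    sched = alternating_schedule(2, 120.0, 60.0)
    return cfg, sched, generate(cfg, sched)


@pytest.fixture(scope="session")
def small_features(small_fixture):
    cfg, sched, recs = small_fixture
    rc = RunConfig()
    F, rejected = extract_features(recs, rc)
    labels = []
    for r in recs:
        w = window(bandpass(r, rc.preprocess), rc.preprocess)
        labels += ground_truth_labels(sched, w, recs[0].start_time, rc.preprocess.window_s)
    return F, np.array(labels), rejected


@pytest.fixture(scope="session")
def e2e_result():
    """Full pipeline on the 2 x 10-min desk-scale fixture with planted states."""
    cfg = SynthConfig(n_channels=8, fs=500.0, file_length_s=600.0, n_files=2, seed=1)
    sched = alternating_schedule(2, 600.0, 120.0)
    recs = generate(cfg, sched)
    rc = RunConfig(cluster=ClusterConfig(seed=1))
    result = run(recs, rc)
    labels = []
    for r in recs:
        w = window(bandpass(r, rc.preprocess), rc.preprocess)
        labels += ground_truth_labels(sched, w, recs[0].start_time, rc.preprocess.window_s)
    return result, np.array(labels)
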