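import logging

import numpy as np
import pytest

from ecgpsr import (PipelineConfig, default_healthy_spec, generate_record,
                    preprocess)

logging.getLogger("ecgpsr").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def zero_jitter_record():
    """10 healthy beats with perfectly repeatable morphology."""
    spec = default_healthy_spec(duration_jitter=0.0, amplitude_jitter=0.0,
                                rr_jitter=0.0)
    return generate_record(10, 0, healthy_spec=spec, seed=3)


@pytest.fixture(scope="session")
def healthy_record():
    """10 healthy beats with the default (small) jitters."""
    return generate_record(10, 0, seed=1)


@pytest.fixture(scope="session")
def transition_record():
    """45 healthy beats followed by 45 long-QT-like beats."""
    return generate_record(45, 45, seed=1)


@pytest.fixture(scope="session")
def preprocessed(zero_jitter_record):
    return preprocess(zero_jitter_record.signal)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


def match_beats_to_truth(beats, truth):
    """Index of the nearest ground-truth beat for each detected beat."""
    truth_r = truth["r_peak"].to_numpy()
    return np.array([int(np.argmin(np.abs(truth_r - b.r_peak)))
                     for b in beats])
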