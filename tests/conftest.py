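import numpy as np
import pytest

from fallkit import features as ft
from fallkit import simulator as sim
from fallkit import svm as sv
from fallkit import training as tr
from fallkit.signals import AccelTrace


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def static_trace():
    """3 s of standing still: gravity (0, 0, 1) g, no noise."""
    n = 600
    xyz = np.tile([0.0, 0.0, 1.0], (n, 1))
    return AccelTrace.from_samples(xyz, fs=200.0)


@pytest.fixture()
def random_trace(rng):
    return AccelTrace.from_samples(rng.normal(0, 0.5, size=(1000, 3)), fs=200.0)


@pytest.fixture(scope="session")
def small_protocol():
    """3 subjects x 21 ADLs x 4 trials, with cached features."""
    proto = sim.generate_protocol(3, 4, seed=7)
    feats = {e.path: ft.extract_features(proto.traces[e.path]) for e in proto.manifest}
    return proto, feats


@pytest.fixture(scope="session")
def trained_model(small_protocol):
    """SVM trained on half of the small protocol; returns model + halves."""
    proto, feats = small_protocol
    train_half, test_half = tr.split_cv(proto.manifest, "by_trial", seed=7)
    data = tr.assemble_training_set(
        train_half, lambda e: feats[e.path], select=2, seed=7, frame_stride=10
    )
    model = sv.train(data)
    return model, data, train_half, test_half
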