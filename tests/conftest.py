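import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """6 subjects x 4 features with distinguishable values and both classes."""
    from specnet import SpectraDataset

    mat = np.arange(24, dtype=float).reshape(6, 4)
    labels = ["control", "control", "control", "patient", "patient", "patient"]
    return SpectraDataset(
        intensities=mat,
        labels=np.array(labels, dtype=object),
        feature_ids=["f0", "f1", "f2", "f3"],
        subject_ids=[f"S{i}" for i in range(6)],
    )
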