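import numpy as np
import pytest

from emgrasp.experiment import ExperimentConfig, build_feature_datasets
from emgrasp.simulate import GeneratorConfig, generate_recording


@pytest.fixture(scope="session")
def small_feature_dataset():
    """One subject, 2 reps, every 8th window: 450 x 66 features."""
    config = ExperimentConfig(
        generator=GeneratorConfig(n_reps=2, seed=1), window_stride=8, seed=1)
    return build_feature_datasets(config)[0]


@pytest.fixture(scope="session")
def one_trial_windows():
    """All 38 windows of a single preprocessed default trial."""
    from emgrasp.preprocess import preprocess_recording, segment
    rec = generate_recording(GeneratorConfig(seed=3), 0, 0, 4, 0)
    return segment(preprocess_recording(rec))


def gaussian_classes(rng, means, cov_scale=1.0, n_per_class=200, dim=None):
    """Labeled isotropic Gaussian clusters around the given means."""
    means = np.atleast_2d(np.asarray(means, dtype=float))
    dim = dim or means.shape[1]
    X = np.vstack([
        mean + cov_scale * rng.standard_normal((n_per_class, dim))
        for mean in means])
    y = np.repeat(np.arange(len(means)), n_per_class)
    return X, y
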