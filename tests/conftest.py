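import numpy as np
import pandas as pd
import pytest

from pmfvar.feature_matrix import PeakMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, features=None, samples=None, labels=None,
                mode="intensity"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if features is None:
        features = 1000.0 + 10.0 * np.arange(m)
    if samples is None:
        samples = [f"s{i:02d}" for i in range(n)]
    lab = None
    if labels is not None:
        lab = pd.DataFrame(
            {"family": list(labels)},
            index=pd.Index(samples, name="sample_id"),
        )
    return PeakMatrix(features=np.asarray(features, dtype=float),
                      samples=list(samples), values=values, mode=mode,
                      labels=lab)


@pytest.fixture
def two_group_matrix():
    """4 samples, 2 families, 3 features, clear group separation."""
    values = [
        [10.0, 5.0, 0.2],
        [9.0, 6.0, 0.1],
        [0.5, 4.0, 12.0],
        [0.3, 5.0, 11.0],
    ]
    return make_matrix(values, labels=["A", "A", "B", "B"])
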