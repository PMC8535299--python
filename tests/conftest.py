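import numpy as np
import pytest
from hypothesis import settings

import diabfuse as df

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def schema():
    return df.default_schema()


@pytest.fixture
def make_dataset(schema):
    """Factory for small complete datasets with reproducible Gaussian features."""

    def _make(n=40, seed=0, separation=1.0, missing_rate=0.0):
        spec = df.SyntheticSpec(
            sources=(("test", n),),
            seed=seed,
            separation=separation,
            missing_rate=missing_rate,
        )
        return df.generate(spec, schema)[0]

    return _make


@pytest.fixture
def blobs():
    """Well-separated standardized 2-feature two-class blobs."""

    def _make(n=200, sep=4.0, seed=0, d=2):
        rng = np.random.default_rng(seed)
        labels = (rng.random(n) < 0.5).astype(int)
        X = rng.normal(0.0, 1.0, size=(n, d))
        X[labels == 1] += sep / np.sqrt(d)
        return X, labels

    return _make
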