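import numpy as np
import pytest

from onebitmc import ObservedMatrix


def observed_from_array(values) -> ObservedMatrix:
    """Build an ObservedMatrix from a nested list with 0 meaning unknown."""
    values = np.asarray(values, dtype=np.int8)
    p, q = values.shape
    return ObservedMatrix(
        [f"m{i + 1}" for i in range(p)],
        [f"d{j + 1}" for j in range(q)],
        values,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_observed(rng, p, q, obs_frac=0.8) -> ObservedMatrix:
    """Random +/-1 matrix with an independent Bernoulli observation mask."""
    labels = rng.choice([1, -1], size=(p, q)).astype(np.int8)
    mask = rng.random((p, q)) < obs_frac
    if not mask.any():
        mask[0, 0] = True
    return observed_from_array(np.where(mask, labels, 0))
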