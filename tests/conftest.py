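import numpy as np
import pytest

import poismix as pm


@pytest.fixture(scope="session")
def blocks_data():
    """One medium blocks dataset with ground truth, shared across tests."""
    spec = pm.BlocksSpec(seed=11)
    X, labels, truth = pm.generate_blocks_dataset(spec, 1000)
    return {"spec": spec, "X": X, "labels": labels, "truth": truth}


@pytest.fixture(scope="session")
def normalized_blocks(blocks_data):
    """The same stimuli after exact feedforward normalization."""
    Xn = pm.feedforward_normalize(blocks_data["X"], blocks_data["spec"].A, "plain")
    return {**blocks_data, "Xn": Xn}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_constrained_instance(rng, n_classes=3, n_pixels=6, A=12.0, n_points=5):
    """Random row-normalized fields plus small integer stimuli."""
    W = rng.uniform(0.2, 3.0, size=(n_classes, n_pixels))
    W = pm.normalize_fields(W, A)
    y = rng.integers(0, 6, size=(n_points, n_pixels)).astype(float)
    return W, y
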