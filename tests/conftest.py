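import numpy as np
import pytest

from nirclda.dataset import SpectralDataset
from nirclda.synthetic import SyntheticSpec, generate


@pytest.fixture
def toy_two_class():
    """Hand-computable two-class instance in d=3.

    Both within-class difference vectors are (0,1,0), so range(S_W) is the
    y-axis; the common vectors are (1,0,0) and (0,0,1), and the single
    discriminant direction is (1,0,-1)/sqrt(2).
    """
    X = np.array([
        [1.0, 0.0, 0.0],
        [1.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.0, 1.0, 1.0],
    ])
    y = np.array(["a", "a", "b", "b"])
    return SpectralDataset(absorbance=X, axis=[1.0, 2.0, 3.0], labels=y)


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic conditions: 4 origins x 60 samples, 228 channels."""
    return generate(SyntheticSpec(seed=11))


def random_small_instance(rng, d=None, M=None, C=3):
    """Random small-sample instance where the d x d scatter is formable."""
    d = d if d is not None else int(rng.integers(8, 21))
    C = int(C)
    per = max(2, (M if M is not None else int(rng.integers(C * 2, 13))) // C)
    per = min(per, (d - 1) // C + 1)  # keep the small-sample regime d > M-C
    X = rng.normal(size=(per * C, d))
    y = np.repeat([f"c{i}" for i in range(C)], per)
    return X, y
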