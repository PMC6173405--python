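import numpy as np
import pytest

from qrfdrug import Dataset, GeneratorSpec, fit_forest, generate


@pytest.fixture(scope="session")
def skewed_panel():
    """Small heteroscedastic skewed-noise panel with 2 informative features."""
    return generate(GeneratorSpec(n=150, M=12, s=2, mutation_fraction=0.25, seed=11))


@pytest.fixture(scope="session")
def skewed_forest(skewed_panel):
    data, _ = skewed_panel
    return fit_forest(data, T=50, seed=7)


@pytest.fixture()
def tiny_dataset():
    """Deterministic 12 x 3 dataset with a strong first feature."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(12, 3))
    y = 2.0 * X[:, 0] + 0.1 * rng.normal(size=12)
    return Dataset(X, y, [f"s{i}" for i in range(12)], ["f0", "f1", "f2"])
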