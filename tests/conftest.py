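import numpy as np
import pytest

from iefs import ExpressionDataset, RunConfig, SyntheticSpec, generate


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """4 samples x 2 genes, labels {A, A, B, B}."""
    return ExpressionDataset(
        matrix=np.array([[1.0, 2.0], [1.5, 2.5], [9.0, 8.0], [8.5, 7.5]]),
        feature_ids=["g1", "g2"],
        sample_ids=["s1", "s2", "s3", "s4"],
        labels=np.array(["A", "A", "B", "B"], dtype=object),
    )


@pytest.fixture
def small_synth():
    """3-class imbalanced dataset with planted signal, desk-scale."""
    spec = SyntheticSpec(class_sizes=(30, 10, 10), n_features=120,
                         n_informative_per_class=8, effect_size=2.0, seed=7)
    return generate(spec)


@pytest.fixture
def separable_synth():
    """Strong-signal dataset every classifier should nail on training data."""
    spec = SyntheticSpec(class_sizes=(20, 8, 8), n_features=60,
                         n_informative_per_class=6, effect_size=8.0, seed=11)
    return generate(spec)


def random_binary_instance(rng, n_samples=40, n_features=12):
    """A random continuous feature matrix with a weakly informative
    binary label, as used by the selector-vs-oracle comparisons."""
    X = rng.normal(size=(n_samples, n_features))
    w = rng.normal(size=n_features)
    y = (X @ w + rng.normal(scale=0.5, size=n_samples)) > 0
    if y.all() or not y.any():
        y[0] = not y[0]
    return X, y
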