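import numpy as np
import pytest

from bdaselect import FeatureTable


@pytest.fixture
def separable_table() -> FeatureTable:
    """Two well-separated point clusters on the first axis."""
    X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 0.0], [3.0, 1.0]])
    y = np.array([-1, -1, 1, 1])
    return FeatureTable(feature_names=["f1", "f2"], X=X, y=y)


@pytest.fixture
def noisy_table() -> FeatureTable:
    """40 samples, 4 features; feature 0 is the label itself, feature 1 is
    informative-with-noise, features 2-3 are noise."""
    rng = np.random.default_rng(7)
    y = np.repeat([1, -1], 20)
    X = np.column_stack([
        y.astype(float),
        y + 0.8 * rng.normal(size=40),
        rng.normal(size=40),
        rng.normal(size=40),
    ])
    return FeatureTable(feature_names=list("abcd"), X=X, y=y)


@pytest.fixture
def csv_path(tmp_path):
    p = tmp_path / "data.csv"
    p.write_text(
        "f1,f2,label\n"
        "0.1,3,case\n"
        "0.4,1,control\n"
        "0.9,2,case\n"
        "0.3,5,control\n")
    return p
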