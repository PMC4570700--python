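import numpy as np
import pytest

from autoqsar import Dataset, FixtureSpec, make_linear


@pytest.fixture
def linear_ds():
    """Default linear fixture: n=200, 3 informative + 7 noise, pop R² ≈ 0.9."""
    ds, meta = make_linear(FixtureSpec("linear", seed=11))
    return ds, meta


@pytest.fixture
def tiny_exact_ds():
    """Noiseless y = 2·x + 1 on a single feature, n=20."""
    x = np.linspace(-2.0, 2.0, 20)
    return Dataset(response_name="y", y=2 * x + 1, feature_names=["x"], X=x[:, None])


def write_csv(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path
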