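import numpy as np
import pytest

from crosslatent import DataView, GeneratorSpec, PairedDataset, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_view(values, prefix="f", ids=None):
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    ids = ids if ids is not None else [f"s{i + 1}" for i in range(n)]
    return DataView(values, [f"{prefix}{j + 1}" for j in range(d)], ids)


def make_paired(x, y, confounds=None):
    return PairedDataset(
        make_view(x, "x"),
        make_view(y, "y"),
        None if confounds is None else make_view(confounds, "c"),
    )


@pytest.fixture
def centered_pair(rng):
    """Independent centered Gaussian views, 20 x 6 and 20 x 4."""
    x = rng.standard_normal((20, 6))
    y = rng.standard_normal((20, 4))
    return x - x.mean(axis=0), y - y.mean(axis=0)


@pytest.fixture
def one_effect_dataset():
    """A paired dataset with a single strong planted effect plus its truth."""
    spec = GeneratorSpec(
        n=120, p=16, q=16, n_effects=1, support_fraction=0.25,
        effect_strengths=(3.0,), noise_sd=1.0, seed=42,
    )
    return generate(spec)
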