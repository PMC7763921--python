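import numpy as np
import pytest

from entroprof import logistic_map, preset_config


def quantized_series(kind: str, n: int, seed: int, decimals: int = 2) -> np.ndarray:
    """Random test series rounded to a fixed resolution.

    Rounding mirrors the finite resolution of recorded RR intervals and
    deliberately creates tied distances — the stress case for the
    data-driven range set (continuous data trivially has all-distinct
    bins).
    """
    rng = np.random.default_rng(seed)
    if kind == "uniform":
        values = rng.uniform(size=n)
    elif kind == "gaussian":
        values = rng.normal(size=n)
    elif kind == "logistic":
        values = logistic_map(preset_config("chaotic", n=n, seed=seed)).values
    else:
        raise ValueError(kind)
    return np.round(values, decimals)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
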