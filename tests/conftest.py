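import numpy as np
import pytest

from polyquant import Baseline, Region
from polyquant.deconvolve import GaussianPeak

# Shared three-Gaussian construction: sharp, well-separated peaks inside a
# restricted region, the setting in which peak deconvolution is meaningful.
THREE_PEAK_L = 500
THREE_PEAK_TRUTH = (
    GaussianPeak(mu=170.0, sigma=8.0, height=1.0),
    GaussianPeak(mu=250.0, sigma=8.0, height=0.8),
    GaussianPeak(mu=330.0, sigma=8.0, height=1.2),
)
THREE_PEAK_REGION = Region("Subunits", 130, 370)
THREE_PEAK_NOISE_SD = 0.012  # 1% of the tallest peak
THREE_PEAK_SMOOTHING = 11
THREE_PEAK_HALF_WINDOW = 35


def three_peak_signal(noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    x = np.arange(THREE_PEAK_L, dtype=float)
    y = sum(p(x) for p in THREE_PEAK_TRUTH)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, THREE_PEAK_L)
    return y


@pytest.fixture
def zero_baseline() -> Baseline:
    return Baseline(channel="uv", value=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
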