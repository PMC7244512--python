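import numpy as np
import pytest

from corticalhue import HueModel, LayerConfig, default_config
from corticalhue.analysis import measure_all_tunings


@pytest.fixture(scope="session")
def model() -> HueModel:
    """The default (paper-scale) model, calibrated once per session."""
    return HueModel(default_config()).calibrate()


@pytest.fixture(scope="session")
def curves(model):
    """All tuning curves of the default model over the 60-hue stimulus set."""
    return measure_all_tunings(model)


@pytest.fixture(scope="session")
def small_model() -> HueModel:
    """A spatially downscaled model (tiny receptive fields, 32 px images) for
    oracle comparisons where the direct convolution sum must stay cheap."""
    cfg = LayerConfig(
        image_size=32,
        rf_sizes={"mLGN": 5, "mV1": 7, "mV2": 9, "mV4": 11},
        sigma_mv1=7 / 6,
        sigma_mv2=9 / 6,
        sigma_mv4=11 / 6,
    )
    return HueModel(cfg).calibrate()


def direct_gaussian_convolve(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Independent oracle: same-size 2-D convolution with edge replication,
    computed as an explicit windowed sum."""
    k = kernel.shape[0]
    r = k // 2
    padded = np.pad(img, r, mode="edge")
    out = np.empty_like(img, dtype=float)
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            out[y, x] = np.sum(padded[y : y + k, x : x + k] * kernel)
    return out
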