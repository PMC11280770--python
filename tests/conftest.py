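import numpy as np
import pytest

from ebdl import SyntheticConfig, TFRSample, gen_band_task, normalized_freq_axis


@pytest.fixture(scope="session")
def small_band_dataset():
    """A small 2-class band task shared by several training-level tests."""
    cfg = SyntheticConfig(n_classes=2, samples_per_class=24, tfr_shape=(16, 32),
                          class_bands=[(-0.4, 0.3), (0.4, 0.3)], noise_sd=0.05,
                          power_ratio_db=6.0, seed=11)
    return gen_band_task(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_tfr(values: np.ndarray, label: int = 0, subject: str = "") -> TFRSample:
    values = np.asarray(values, dtype=float)
    return TFRSample(values=values, freq_axis=normalized_freq_axis(values.shape[1]),
                     label=label, subject_id=subject)
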