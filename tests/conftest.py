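import numpy as np
import pytest

from aoldv import OpticalConfig


@pytest.fixture(scope="session")
def cfg() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture(scope="session")
def small_cfg() -> OpticalConfig:
    """Acquisition config with few frames for fast end-to-end runs."""
    return OpticalConfig(frames_per_acquisition=10)


def step_spectrum(n_bins: int, cutoff_bin: int, level: float = 1.0, floor: float = 0.0):
    """Noise-free step spectrum: `level` up to `cutoff_bin`, `floor` beyond."""
    from aoldv import PowerSpectrum

    df = 1.0 / 0.03
    freqs = np.arange(1, n_bins + 1) * df
    power = np.where(np.arange(1, n_bins + 1) <= cutoff_bin, level, floor)
    return PowerSpectrum(freqs, power)
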