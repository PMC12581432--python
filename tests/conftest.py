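import numpy as np
import pytest

from oscillotype import AnalysisConfig, Recording
from oscillotype.synthetic_data import GammaSimConfig, gen_gamma_lfp


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def tone_40hz():
    """120 s pure 40 Hz sinusoid, amplitude 100 µV, at the study's 5 kHz."""
    fs = 5000.0
    t = np.arange(int(120 * fs)) / fs
    return Recording(0.1 * np.sin(2 * np.pi * 40.0 * t), fs, label="tone40")


@pytest.fixture(scope="session")
def white_noise_120s():
    rng = np.random.default_rng(123)
    return Recording(rng.standard_normal(600000) * 0.05, 5000.0, label="white")


@pytest.fixture(scope="session")
def gamma_sim():
    """Default-condition synthetic gamma LFP (34 Hz, 120 s) with truth."""
    return gen_gamma_lfp(GammaSimConfig(seed=42))
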