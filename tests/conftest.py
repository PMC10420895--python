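import numpy as np
import pytest

from lacto2d import corr2d
from lacto2d.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The full 130-sample synthetic study at the default settings."""
    return generate_dataset(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def calibration(default_dataset):
    return default_dataset.calibration


@pytest.fixture(scope="session")
def fresh_reference(calibration):
    """Mean fresh (label-A) calibration spectrum: the 2D-correlation reference."""
    return corr2d.reference_spectrum(calibration.where_label("A"))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
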