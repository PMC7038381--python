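import numpy as np
import pytest

from etongue import DatasetSpec, ExcitationSpec, generate_beverage_dataset

# short two-segment programme (4.5 s active in a 6 s cycle, 900 points)
SHORT_EXCITATION = dict(
    segment_frequencies=(1.0, 2.0),
    pulse_amplitudes=(1.0, 0.6, 0.2),
    cycle_duration=6.0,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small simulated dataset for fast protocol tests:
    3 classes x 2 concentrations x 2 replicates = 12 samples of 6 x 900."""
    spec = DatasetSpec(
        class_names=("beer", "black tea", "red wine"),
        concentrations=(0.25, 1.0),
        replicates=2,
        excitation=ExcitationSpec(**SHORT_EXCITATION),
        seed=7,
    )
    return generate_beverage_dataset(spec)


@pytest.fixture(scope="session")
def small_full_design():
    """Full 7x3x3 beverage design at reduced record length (6 x 900)."""
    spec = DatasetSpec(excitation=ExcitationSpec(**SHORT_EXCITATION), seed=11)
    return generate_beverage_dataset(spec)
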