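import numpy as np
import pytest

import salientsort as ss


@pytest.fixture
def three_unit_channel() -> ss.SpikeMatrix:
    """A well-separated 3-unit channel at SNR 8 (750 spikes)."""
    matrix, _ = ss.simulate_channel(
        {"n_units": 3, "n_spikes": 750, "snr": 8.0, "seed": 42}
    )
    return matrix


@pytest.fixture
def two_unit_channel() -> ss.SpikeMatrix:
    matrix, _ = ss.simulate_channel(
        {"n_units": 2, "n_spikes": 500, "snr": 8.0, "seed": 7}
    )
    return matrix


@pytest.fixture
def tiny_labeled_matrix() -> ss.SpikeMatrix:
    """Hand-sized labeled matrix: 2 classes x 3 spikes x 4 features."""
    waveforms = np.array([
        [0, 2, 1, 5],
        [2, 2, 1, 5],
        [1, 2, 1, 5],
        [10, 0, 1, 5],
        [12, 0, 1, 5],
        [11, 0, 1, 5],
    ])
    labels = np.array(["a", "a", "a", "b", "b", "b"])
    return ss.SpikeMatrix(waveforms=waveforms, labels=labels)
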