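import numpy as np
import pytest
from hypothesis import settings

import mstates as ms

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def montage():
    return ms.standard_1020_montage()


@pytest.fixture(scope="session")
def small_montage():
    # 4 channels on a ring: enough for GFP / clustering toy examples
    pos = np.array(
        [[1.0, 0, 0.2], [0, 1.0, 0.2], [-1.0, 0, 0.2], [0, -1.0, 0.2]]
    )
    return ms.Montage(["a", "b", "c", "d"], pos)


@pytest.fixture(scope="session")
def planted_recording(montage):
    """One subject at the study conditions: 4 states, SNR 4, 100 ms mean
    duration, 60 s at 250 Hz, 19 channels."""
    templates = ms.generate_templates(4, montage, 0.5, seed=1)
    labels = ms.generate_label_sequence(
        4, 15000, 250.0, 100.0, seed=2, min_samples=13
    )
    rec, truth = ms.generate_eeg(
        templates, labels, 250.0, snr=4.0, seed=3, montage=montage
    )
    return rec, truth
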