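import numpy as np
import pytest

from strokelab.experiments import measure_occlusion_drops


@pytest.fixture(scope="session")
def occlusion_drops():
    """Full occlusion-confirmation harness: synthetic speckle stacks with a
    five-fold vessel and 2.5-fold core decorrelation-time increase, run
    through the complete contrast -> BFI -> ROI-drop chain."""
    return measure_occlusion_drops(shape=(256, 256), n_frames=100, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
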