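import numpy as np
import pytest

from radarcyto import pipeline
from radarcyto.fcs_io import ChannelMeta, EventMatrix


@pytest.fixture(scope="session")
def reference_bundle():
    """Merged 1-normal + 3-leukemic reference with the optimized
    normal-vs-blast layout (expensive; built once per session)."""
    return pipeline.build_reference(seed=0)


@pytest.fixture(scope="session")
def position_reference():
    """Tube-1 position-classification calibration (layout + gates)."""
    return pipeline.build_position_reference(seed=0, tube=1)


def make_matrix(values, markers, labels=None, origin=None):
    channels = [ChannelMeta(marker=mk, detector=mk) for mk in markers]
    return EventMatrix(np.asarray(values, dtype=float), channels,
                       labels=labels, origin=origin)


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(11)
    return make_matrix(rng.normal(2.0, 1.0, size=(40, 3)),
                       ["CD19", "CD10", "CD45"])
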