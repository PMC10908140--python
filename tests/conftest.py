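import numpy as np
import pytest

from capseeg.data import (SegmentSet, SynthConfig, synth_generate, to_binary)


@pytest.fixture(scope="session")
def synth_small():
    """Five-class synthetic set, 20 segments per class."""
    return synth_generate(SynthConfig(n_per_class=20, seed=42))


@pytest.fixture(scope="session")
def synth_binary_small(synth_small):
    return to_binary(synth_small)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_segments(signals, labels, scheme="five_class"):
    return SegmentSet(signals=np.asarray(signals, dtype=float),
                      labels=np.asarray(labels, dtype=int),
                      label_scheme=scheme)
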