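import numpy as np
import pytest

import serspipe


@pytest.fixture(scope="session")
def default_dataset():
    """Standard synthetic run: 600 x 400, three 6-sigma events, slow drift."""
    cfg = serspipe.default_config(seed=0)
    return serspipe.generate_dataset(cfg)


@pytest.fixture(scope="session")
def analyzed(default_dataset):
    """The standard run pushed through background removal, detection, merging."""
    m, gt = default_dataset
    cs = serspipe.remove_background(m)
    det = serspipe.detect_signals(cs)
    sigs = serspipe.merge_signals(cs, det)
    return m, gt, cs, det, sigs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
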