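import numpy as np
import pytest

from pelagia import demo


@pytest.fixture
def demo_tree():
    return demo.demo_chronogram()


@pytest.fixture
def demo_records():
    return demo.demo_records()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
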