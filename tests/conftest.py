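import numpy as np
import pytest

from fungpcr.synthetic import (
    GeneratorConfig,
    make_af_fixture,
    make_cnn_benchmark,
    make_gpcr_like,
    make_screen_bundle,
)


@pytest.fixture(scope="session")
def gpcr_set():
    """Five 7-helix receptor-like records with ground-truth topology."""
    return make_gpcr_like(5, GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def screen_bundle():
    return make_screen_bundle(seed=11, n_per_class=2)


@pytest.fixture(scope="session")
def af_pair_good():
    return make_af_fixture(2, q=1.0, seed=5)


@pytest.fixture(scope="session")
def af_pair_bad():
    return make_af_fixture(2, q=0.0, seed=5)


@pytest.fixture(scope="session")
def small_benchmark():
    """300/class separable benchmark for quick training tests."""
    return make_cnn_benchmark(300, 300, seed=7)


@pytest.fixture(scope="session")
def trained_small(small_benchmark):
    from fungpcr.cnn import Cnn1dClassifier, train

    pos, neg = small_benchmark
    model = Cnn1dClassifier(seed=7)
    return train(model, pos, neg)
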