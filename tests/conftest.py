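import numpy as np
import pytest

from omicbridge import FeatureMatrix, LabelSet
from omicbridge.simulate import SimScenario, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def tiny_scenario(**kw) -> SimScenario:
    """Small, fast scenario for unit tests (not the study conditions)."""
    base = dict(n_src=80, n_tgt=80, n_clusters=3, latent_dim=6,
                n_features=40, separation=10.0, seed=0)
    base.update(kw)
    return SimScenario(**base)


@pytest.fixture
def tiny_data():
    return simulate(tiny_scenario())


@pytest.fixture
def toy_matrices():
    src = FeatureMatrix([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
                        ["s1", "s2"], ["A", "B", "C"], "source")
    tgt = FeatureMatrix([[7.0, 8.0, 9.0], [1.0, 0.0, 2.0]],
                        ["t1", "t2"], ["B", "C", "D"], "target")
    return src, tgt


@pytest.fixture
def toy_labels():
    return LabelSet({"s1": "B cell", "s2": "T cell"})
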