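import numpy as np
import pytest

from gemusica import ExpressionMatrix, ScaleConfig


def make_matrix(values, probe_ids=None, sample_ids=None, scale_tag="log2"):
    values = np.asarray(values, float)
    probe_ids = probe_ids or tuple(f"p{i}" for i in range(values.shape[0]))
    sample_ids = sample_ids or tuple(f"s{j}" for j in range(values.shape[1]))
    return ExpressionMatrix(tuple(probe_ids), tuple(sample_ids), values, scale_tag)


@pytest.fixture
def tiny_matrix():
    # 4 probes x 3 samples, log2 scale, contains a within-column tie (column s1)
    return make_matrix(
        [[1, 5, 3], [3, 7, 4], [2, 2, 9], [5, 5, 5]],
        probe_ids=("pA", "pB", "pC", "pD"),
        sample_ids=("s0", "s1", "s2"),
    )


@pytest.fixture
def default_scale():
    return ScaleConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20160630)
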