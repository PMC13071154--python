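import numpy as np
import pytest

from etpfam.synthetic import BenchmarkSpec, generate_benchmark
from etpfam.window_scoring import PositionScoreTrack


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Small full-pipeline benchmark shared by the slower tests."""
    spec = BenchmarkSpec(
        n_families=6, embed_dim=8, n_sequences=90,
        sequence_length_range=(40, 80), seed=7,
    )
    return generate_benchmark(spec)


def random_track(rng, n_pos=None, K=None, seq_id="s", model_id="m"):
    n_pos = n_pos or int(rng.integers(1, 50))
    K = K or int(rng.integers(2, 20))
    scores = rng.random((n_pos, K)) + 1e-6
    scores /= scores.sum(axis=1, keepdims=True)
    positions = np.cumsum(rng.integers(1, 5, size=n_pos))
    return PositionScoreTrack(seq_id, model_id, positions, scores)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
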