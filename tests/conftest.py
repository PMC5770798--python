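import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hspkit.seqio import AMINO_ACIDS, ProteinSequence

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_seq(rng):
    """Factory for random sequences over the standard alphabet."""

    def make(length: int, seq_id: str = "rand") -> ProteinSequence:
        codes = rng.integers(0, 20, size=length)
        return ProteinSequence(
            id=seq_id, residues="".join(AMINO_ACIDS[c] for c in codes)
        )

    return make


@pytest.fixture
def toy_clouds(rng):
    """Two well-separated 2-D point clouds (linearly separable)."""
    import pandas as pd

    n = 20
    a = rng.normal(loc=(-2.0, -2.0), scale=0.3, size=(n, 2))
    b = rng.normal(loc=(2.0, 2.0), scale=0.3, size=(n, 2))
    X = pd.DataFrame(np.vstack([a, b]), columns=["x1", "x2"])
    y = np.array(["neg"] * n + ["pos"] * n)
    return X, y


@pytest.fixture
def xor_clusters(rng):
    """Four tight clusters in the XOR pattern (not linearly separable)."""
    import pandas as pd

    n = 20
    centers = [((0, 0), "a"), ((1, 1), "a"), ((0, 1), "b"), ((1, 0), "b")]
    rows, labels = [], []
    for (cx, cy), lab in centers:
        rows.append(rng.normal(loc=(cx, cy), scale=0.08, size=(n, 2)))
        labels.extend([lab] * n)
    X = pd.DataFrame(np.vstack(rows), columns=["x1", "x2"])
    return X, np.array(labels)
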