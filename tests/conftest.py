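import numpy as np
import pytest

from pottsprof.mi import MetricMatrix
from pottsprof.potts import PottsModel
from pottsprof.profiles import ProfileTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_model(L: int, Q: int, rng, scale: float = 1.0) -> PottsModel:
    """Random lattice-gas-gauge Potts model."""
    model = PottsModel.zeros(L, Q)
    model.h[:, 1:] = rng.uniform(-scale, scale, size=(L, Q))
    for a in range(L):
        for b in range(a + 1, L):
            block = rng.uniform(-scale, scale, size=(Q, Q))
            model.J[a, b, 1:, 1:] = block
            model.J[b, a, 1:, 1:] = block.T
    return model


def random_table(N: int, L: int, Q: int, rng) -> ProfileTable:
    setting = "standard" if Q == 1 else "evolutionary"
    return ProfileTable(
        row_ids=[f"r{i}" for i in range(N)],
        og_ids=[f"og{j}" for j in range(L)],
        D=rng.integers(0, Q + 1, size=(N, L)),
        setting=setting,
    )


def metric_from_pair_values(values: dict[tuple[str, str], float]) -> MetricMatrix:
    """Build a MetricMatrix from explicit pair scores (test helper)."""
    ids = sorted({og for p in values for og in p})
    idx = {og: k for k, og in enumerate(ids)}
    scores = np.full((len(ids), len(ids)), np.nan)
    for (a, b), s in values.items():
        scores[idx[a], idx[b]] = scores[idx[b], idx[a]] = s
    return MetricMatrix(og_ids=ids, scores=scores, metric_name="SMI")
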