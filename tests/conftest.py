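import numpy as np
import pytest

from multiplexdiff import EmbeddingConfig, ExpressionMatrix, MultiplexNetwork


@pytest.fixture
def expr_small() -> ExpressionMatrix:
    """3 genes x 4 samples with distinct, known variances."""
    values = np.array(
        [
            [1.0, 1.1, 0.9, 1.0],   # low variance
            [0.0, 5.0, 10.0, 2.0],  # high variance
            [1.0, 3.0, 2.0, 4.0],   # medium variance
        ]
    )
    return ExpressionMatrix(["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"], values)


@pytest.fixture
def toy_multiplex() -> MultiplexNetwork:
    """3 nodes, two layers differing in one edge."""
    W1 = np.array([[0.0, 0.7, 0.0], [0.7, 0.0, 0.2], [0.0, 0.2, 0.0]])
    W2 = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.2], [0.9, 0.2, 0.0]])
    return MultiplexNetwork(["A", "B", "C"], {"cond": W2, "base": W1})


def small_config(seed: int = 0, **overrides) -> EmbeddingConfig:
    """Training schedule scaled down for fast test networks."""
    kwargs = dict(k=4, epochs=15, batch_size=256, seed=seed)
    kwargs.update(overrides)
    return EmbeddingConfig(**kwargs)


def random_symmetric_weights(n: int, density: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    W = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < density
    W[iu[0][present], iu[1][present]] = rng.uniform(0, 1, int(present.sum()))
    return W + W.T
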