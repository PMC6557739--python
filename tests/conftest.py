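import numpy as np
import pytest

from scipso.data_io import ExpressionDataset
from scipso.synthetic import SynthSpec, generate


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """4 samples x 3 genes, two balanced classes."""
    values = np.array(
        [
            [1.0, 0.5, 2.0],
            [1.2, 0.4, 1.8],
            [3.0, 0.6, 2.2],
            [3.1, 0.5, 2.1],
        ]
    )
    return ExpressionDataset(
        values=values,
        gene_ids=["gA", "gB", "gC"],
        labels=np.array([1, 1, 2, 2]),
    )


@pytest.fixture
def separable_dataset() -> ExpressionDataset:
    """Two well-separated classes: means +-5, sigma 0.1, 40 samples x 6 genes."""
    rng = np.random.default_rng(42)
    n_per = 20
    X = rng.normal(0.0, 0.1, size=(2 * n_per, 6))
    labels = np.repeat([1, 2], n_per)
    X[:, 0] += np.where(labels == 1, -5.0, 5.0)
    X[:, 1] += np.where(labels == 1, -5.0, 5.0)
    return ExpressionDataset(
        values=X,
        gene_ids=[f"g{i}" for i in range(6)],
        labels=labels,
    )


@pytest.fixture
def planted_dataset():
    """Medium planted-gene dataset used by recovery tests."""
    spec = SynthSpec(
        n_per_class=30,
        n_genes=500,
        n_informative=10,
        effect_size=3.0,
        seed=11,
    )
    return generate(spec)
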