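import numpy as np
import pytest

from amfeskit.data_io import ExpressionDataset
from amfeskit.synthetic import SyntheticSpec, generate_dataset


def row_standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return (x - x.mean()) / x.std()
    return (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """3 genes × 4 samples, labels (1,1,0,0)."""
    return ExpressionDataset(
        gene_ids=["G1", "G2", "G3"],
        sample_ids=["S1", "S2", "S3", "S4"],
        values=np.array([[1.0, 2.0, 3.0, 4.0],
                         [4.0, 3.0, 2.0, 1.0],
                         [0.5, 0.5, 0.5, 0.5]]),
        labels=np.array([1, 1, 0, 0]),
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """Small labeled dataset with 10 planted genes at 2 SD (session-cached)."""
    spec = SyntheticSpec(
        n_genes=120, n_informative=10, n_samples_per_class=15,
        effect_size=2.0, seed=42,
    )
    return generate_dataset(spec)
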