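import numpy as np
import pytest

from declust import ExpressionMatrix, StrainDesign, SyntheticSpec, simulate_counts


@pytest.fixture
def small_counts() -> ExpressionMatrix:
    """3 genes x 4 samples, no zeros."""
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["a1", "a2", "b1", "b2"],
        values=np.array([[1.0, 2.0, 4.0, 8.0], [5.0, 5.0, 5.0, 5.0], [2.0, 8.0, 1.0, 4.0]]),
    )


@pytest.fixture
def small_design() -> StrainDesign:
    return StrainDesign({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})


@pytest.fixture(scope="session")
def default_simulation():
    """One generator draw at the default spec, shared across tests."""
    return simulate_counts(SyntheticSpec(seed=0))


def random_point_cloud(rng: np.random.Generator, n: int) -> np.ndarray:
    """A 2-D cloud with correlated coordinates plus a few offset points,
    roughly the geometry of a mean-space batch."""
    base = rng.normal(0.0, 1.0, size=n)
    pts = np.column_stack([base, base + rng.normal(0.0, 0.15, size=n)])
    n_off = max(1, n // 10)
    idx = rng.choice(n, size=n_off, replace=False)
    pts[idx] += rng.normal(0.0, 2.0, size=(n_off, 2))
    return pts
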