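import numpy as np
import pytest

from gecon.containers import ExpressionMatrix


@pytest.fixture
def worked_profile() -> ExpressionMatrix:
    """Single-gene matrix with the three-value profile used throughout docs."""
    return ExpressionMatrix(
        gene_ids=["G"],
        condition_ids=["T1", "T2", "T3"],
        values=np.array([[343.0, 314.0, 409.0]]),
    )


@pytest.fixture
def random_matrix_factory():
    """Seeded factory of dense random expression matrices (values cross zero)."""

    def make(seed: int, n_genes: int = 20, n_conditions: int = 10) -> ExpressionMatrix:
        rng = np.random.default_rng(seed)
        values = rng.normal(0.0, 200.0, size=(n_genes, n_conditions))
        return ExpressionMatrix(
            gene_ids=[f"g{i}" for i in range(n_genes)],
            condition_ids=[f"c{j}" for j in range(n_conditions)],
            values=values,
        )

    return make
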