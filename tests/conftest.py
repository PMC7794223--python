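import numpy as np
import pytest

from extendscore.exprio import ExpressionMatrix
from extendscore.scoring import GeneSignature


@pytest.fixture
def toy_expr():
    """6 genes x 3 samples; signature uses 1 present constituent + 2 markers."""
    genes = ["C1", "M1", "M2", "B1", "B2", "B3"]
    values = np.array(
        [
            [5.0, 1.0, 4.0],
            [3.0, 2.0, 8.0],
            [9.0, 9.0, 2.0],
            [1.0, 7.0, 6.0],
            [7.0, 5.0, 5.0],
            [2.0, 2.0, 1.0],
        ]
    )
    return ExpressionMatrix(genes, ["S1", "S2", "S3"], values)


@pytest.fixture
def toy_signature():
    # C2 is deliberately absent from toy_expr
    return GeneSignature(("C1", "C2"), ["M1", "M2"], name="toy")


@pytest.fixture
def random_expr():
    def make(n_genes, n_samples, seed=0, scale=100.0):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.0, scale, size=(n_genes, n_samples))
        genes = [f"G{i:05d}" for i in range(n_genes)]
        samples = [f"S{j:04d}" for j in range(n_samples)]
        return ExpressionMatrix(genes, samples, values)

    return make


@pytest.fixture
def random_signature():
    def make(expr, n_markers=11, seed=0):
        rng = np.random.default_rng(seed)
        picks = rng.choice(expr.gene_ids, size=n_markers + 2, replace=False)
        return GeneSignature((picks[0], picks[1]), list(picks[2:]))

    return make
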