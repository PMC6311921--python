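import numpy as np
import pytest

from pcombine import ExpressionMatrix, NullEnsemble, Phenotype


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def toy_ensemble(rng):
    """Seeded uniform (B+1) x m p-value ensemble, tiny enough for the
    loop-based oracle."""
    B, m = 15, 8
    pmat = rng.uniform(1e-4, 1.0, size=(B + 1, m))
    return NullEnsemble(pmat=pmat, B=B, seed=None)


@pytest.fixture
def small_dataset(rng):
    """20-gene, 24-sample matrix with 4 genes weakly tied to the phenotype."""
    m, N = 20, 24
    X = rng.standard_normal((m, N))
    y = X[:4].sum(axis=0) / 4 + 0.8 * rng.standard_normal(N)
    labels = (y > np.median(y)).astype(int)
    return (
        ExpressionMatrix.from_arrays(X),
        Phenotype(labels=labels, raw=y),
    )
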