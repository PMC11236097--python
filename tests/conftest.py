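import numpy as np
import pytest

from sfngrn.io import EdgeList, ExpressionMatrix
from sfngrn.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def tiny_bundle():
    """20-cell bundle for oracle-scale tests."""
    return simulate(
        SimConfig(n_cells=20, n_genes=12, n_tfs=2, targets_per_tf=2, n_clusters=2, seed=101)
    )


@pytest.fixture(scope="session")
def small_bundle():
    """200 cells, 60 genes, 6 TFs x 5 targets — the end-to-end conditions."""
    return simulate(SimConfig(seed=202))


@pytest.fixture(scope="session")
def small_spatial_bundle():
    return simulate(SimConfig(spatial=True, seed=303))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_expression():
    values = np.array(
        [
            [1.0, 0.0, 2.0],
            [0.0, 3.0, 1.0],
            [2.0, 1.0, 0.0],
            [1.0, 1.0, 1.0],
        ]
    )
    return ExpressionMatrix(values, ["c1", "c2", "c3", "c4"], ["g1", "g2", "g3"])


@pytest.fixture()
def toy_truth():
    return EdgeList([("a", "x1"), ("a", "x2")], directed=True)
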