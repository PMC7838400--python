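import numpy as np
import pytest

import lesionconn as lc


@pytest.fixture(scope="session")
def small_table():
    """20-node, 2-module bilateral node table."""
    return lc.generate_node_space(20, 2, seed=1)


@pytest.fixture(scope="session")
def default_world():
    """One fully built synthetic world at study conditions (shared, read-only)."""
    return lc.build_world(lc.PipelineConfig(seed=7, n_perm=500, n_boot=500))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_connectome(rng, n, subject_id="s0"):
    z = rng.normal(0, 0.5, size=(n, n))
    z = (z + z.T) / 2
    np.fill_diagonal(z, 0.0)
    return lc.Connectome(z=z, nodes=np.arange(n), subject_id=subject_id)
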