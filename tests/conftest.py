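import numpy as np
import pytest

from ivafusion import SyntheticConfig, synthesize_multitask
from ivafusion.data_io import pca_whiten


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


@pytest.fixture(scope="session")
def desk_instance():
    """Default desk-scale draw (K=3, N=6, T=120, V=5000) plus reductions."""
    cfg = SyntheticConfig(K=3, N=6, V=5000, T=120, seed=3)
    datasets, truth = synthesize_multitask(cfg)
    reduced = [pca_whiten(ds, 6) for ds in datasets]
    return datasets, truth, reduced


@pytest.fixture(scope="session")
def small_instance():
    """Cheap draw for plumbing tests (K=2, N=3, T=30, V=400)."""
    cfg = SyntheticConfig(K=2, N=3, V=400, T=30, seed=11)
    datasets, truth = synthesize_multitask(cfg)
    reduced = [pca_whiten(ds, 3) for ds in datasets]
    return datasets, truth, reduced
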