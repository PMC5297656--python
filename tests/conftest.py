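import numpy as np
import pytest

from lncterplay.synthetic import SimulationConfig, simulate_dataset
from lncterplay.types import ExpressionMatrix


SMALL_CONFIG = SimulationConfig(
    n_genes=100,
    n_lncrnas=20,
    n_chroms=4,
    n_trans_pairs=4,
    n_extra_de_lnc=2,
    n_extra_de_mrna=8,
    n_sets=10,
    set_size=12,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced synthetic dataset shared by read-only tests."""
    return simulate_dataset(SMALL_CONFIG, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(11)


def make_matrix(values, groups=None):
    """Build an ExpressionMatrix from a 2-D array; columns split half case,
    half control unless a group list is given."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    sample_ids = [f"s{j}" for j in range(n_samples)]
    if groups is None:
        half = n_samples // 2
        groups = ["case"] * half + ["control"] * (n_samples - half)
    return ExpressionMatrix(
        probe_ids=[f"p{i}" for i in range(n_probes)],
        sample_ids=sample_ids,
        groups=dict(zip(sample_ids, groups)),
        values=values,
    )
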