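import numpy as np
import pytest

from nlim import quant
from nlim import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    """Fast generator configuration: no planted motifs, few genes."""
    return sd.SimConfig(n_genes=48, motifs=())


@pytest.fixture(scope="session")
def dataset():
    """One default-configuration dataset (planted motifs included)."""
    return sd.generate_dataset(sd.SimConfig(), seed=11)


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, dataset):
    path = tmp_path_factory.mktemp("synthetic") / "data"
    sd.write_dataset(dataset, path)
    return path


@pytest.fixture(scope="session")
def protein_matrix(dataset):
    conditions, replicates = quant.design_series(dataset.design)
    raw = quant.rollup(dataset.peptides, "global")
    return quant.normalize(raw, conditions, replicates)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
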