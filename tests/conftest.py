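import numpy as np
import pandas as pd
import pytest

from srnaclr.config import GeneratorConfig
from srnaclr.synthetic import generate_compendium, generate_experiment


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """20 sRNAs x 200 genes x 100 arrays with planted regulons."""
    return GeneratorConfig(
        n_genes=200,
        n_srnas=20,
        n_compendium_arrays=100,
        targets_per_srna=(1, 10),
        ybey_dependent_srna_fraction=0.5,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """(compendium, truth, experiment, designs) for the small config."""
    m, truth = generate_compendium(small_cfg)
    exp, designs = generate_experiment(truth, small_cfg)
    return m, truth, exp, designs


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture
def tiny_matrix() -> pd.DataFrame:
    return pd.DataFrame(
        [[1.5, 2.5], [3.5, 4.5]],
        index=["geneA", "geneB"],
        columns=["arr1", "arr2"],
    )
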