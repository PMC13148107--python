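import numpy as np
import pandas as pd
import pytest

from inversepair.profiles import SubtypeProfiles, aggregate_profiles
from inversepair.sc_qc import normalize_cpm_log
from inversepair.synthetic import SimConfig, gen_sc_counts

# small but study-shaped: 12 PN subtypes, 20 cells each, planted caps->Ten-m pair
SMALL_SIM = dict(n_subtypes=12, cells_per_subtype=20, n_genes=300, n_csms=30)

# conditions for planted-partner recovery: >=30 decoy CSMs, study-like subtype count
RECOVERY_SIM = dict(n_subtypes=30, cells_per_subtype=20, n_genes=300, n_csms=34)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SimConfig(**SMALL_SIM, seed=11)
    return gen_sc_counts(cfg)


@pytest.fixture(scope="session")
def small_profiles(small_dataset):
    adata, truth = small_dataset
    nm = normalize_cpm_log(adata)
    return aggregate_profiles(nm), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_profiles(rng, n_subtypes=6, genes=("g1", "g2", "g3")):
    """Hand-rolled random SubtypeProfiles for unit tests."""
    subtypes = [f"S{i}" for i in range(n_subtypes)]
    mean = pd.DataFrame(
        rng.uniform(0, 10, size=(n_subtypes, len(genes))), index=subtypes, columns=genes
    )
    frac = pd.DataFrame(
        rng.uniform(0, 1, size=(n_subtypes, len(genes))), index=subtypes, columns=genes
    )
    n_cells = pd.Series(10, index=pd.Index(subtypes))
    return SubtypeProfiles(mean=mean, fraction=frac, n_cells=n_cells)
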