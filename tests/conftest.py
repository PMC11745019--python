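import numpy as np
import pandas as pd
import pytest

from gvniche.abundance import AbundanceMatrix, build_abundance, presence_filter
from gvniche.config import SimConfig
from gvniche.simulate import LakeSimulator


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated survey shared by read-only tests."""
    return LakeSimulator(SimConfig(seed=11, n_genomes=60))


@pytest.fixture(scope="session")
def small_run(small_sim):
    """Community tables plus the filtered abundance matrix."""
    cov, sheet, genome_table, truth = small_sim.gen_community()
    filtered = presence_filter(build_abundance(cov, sheet))
    return {
        "cov": cov,
        "sheet": sheet,
        "genomes": genome_table,
        "truth": truth,
        "filtered": filtered,
    }


def toy_matrix(values, samples=None, breadth=None, filtered=True):
    """Hand-built AbundanceMatrix for rule-level tests."""
    values = pd.DataFrame(values)
    values.columns = samples if samples is not None else [f"s{i}" for i in range(values.shape[1])]
    if breadth is None:
        breadth = values.where(values <= 0, 1.0).where(values > 0, 0.0)
    else:
        breadth = pd.DataFrame(breadth, index=values.index, columns=values.columns)
    return AbundanceMatrix(values=values, breadth=breadth, filtered=filtered)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
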