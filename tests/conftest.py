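import numpy as np
import pandas as pd
import pytest

import haplosel as h


@pytest.fixture(scope="session")
def small_null_dataset():
    """A small null-scenario dataset shared by read-only tests."""
    cfg = h.SimConfig(n_genes=400, seed=11)
    return h.simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_panel(female_codes, male_codes, gene="g1", pos=100):
    """Build a one-site GenotypePanel from per-individual code lists."""
    from haplosel.sexlinkage import GenotypePanel

    females = [f"F{i}" for i in range(len(female_codes))]
    males = [f"M{i}" for i in range(len(male_codes))]
    individuals = pd.DataFrame(
        {
            "individual": males + females,
            "sex": ["M"] * len(males) + ["F"] * len(females),
        }
    )
    genotypes = pd.DataFrame(
        np.array([male_codes + female_codes], dtype=np.int8),
        index=pd.MultiIndex.from_tuples([(gene, pos)], names=["gene_id", "pos"]),
        columns=males + females,
    )
    return GenotypePanel(individuals=individuals, genotypes=genotypes)
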