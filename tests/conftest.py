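import numpy as np
import pandas as pd
import pytest

from qstfstkit import GenotypeMatrix, PhenotypeTable
from qstfstkit.datatypes import PHENO_COLUMNS
from qstfstkit.simulate import paper_like_config, simulate_dataset, tiny_config


@pytest.fixture(scope="session")
def paper_like_data():
    """One study-scale synthetic dataset shared across read-only tests."""
    cfg = paper_like_config(seed=11, n_loci=2000)
    g, p = simulate_dataset(cfg)
    return cfg, g, p


@pytest.fixture(scope="session")
def tiny_data():
    cfg = tiny_config(seed=5)
    return cfg, *simulate_dataset(cfg)


@pytest.fixture
def toy_genotypes():
    """2 species x 4 individuals x 3 loci, hand-readable."""
    geno = np.array(
        [
            [0, 1, 2],
            [0, 0, 2],
            [1, 0, 2],
            [0, 1, 2],
            [2, 1, 0],
            [2, 2, 0],
            [2, 2, 0],
            [1, 2, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        individual_ids=[f"i{k}" for k in range(8)],
        species=np.array(["A"] * 4 + ["B"] * 4, dtype=object),
        geno=geno,
        locus_ids=["l0", "l1", "l2"],
    ).validate()


def make_phenotypes(rows):
    """rows: (individual, species, site, accession, trait, value)."""
    return PhenotypeTable(pd.DataFrame(rows, columns=PHENO_COLUMNS))
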