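import numpy as np
import pandas as pd
import pytest

from lnchet import preprocess
from lnchet.matrix import LOG2_TPM1, TPM, ZSCORE, ExpressionMatrix
from lnchet.simulate import SimConfig, generate_cohort, generate_population_pairs


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with all planted structure, shared across tests."""
    cfg = SimConfig(
        n_groups=3,
        cells_per_group=30,
        n_lnc=300,
        n_coding=100,
        n_modules=2,
        module_size=20,
        stemness_set_size=15,
        subtype_set_sizes=(6, 6, 6, 6),
        n_multivariant_genes=5,
        variants_per_gene=10,
        seed=11,
    )
    return cfg, *generate_cohort(cfg)


@pytest.fixture(scope="session")
def processed(small_cohort):
    """(logged, genes, cells, z) for the small cohort."""
    _cfg, m, meta, _annot, _truth = small_cohort
    logged = preprocess.log_transform(m)
    genes = preprocess.select_genes(logged, meta)
    cells = preprocess.select_cells(logged, genes)
    z = preprocess.zscore(logged.subset(features=genes, samples=cells))
    return logged, genes, cells, z


@pytest.fixture(scope="session")
def population_pairs(small_cohort):
    _cfg, m, meta, _annot, truth = small_cohort
    return generate_population_pairs(m, meta, truth, top_frac=0.25)


def make_matrix(values, features=None, samples=None, space=TPM):
    arr = np.asarray(values, dtype=float)
    features = features or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"c{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=features, columns=samples), space)


def make_meta(samples, groups, kind="single_cell", pair_id=None):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "group": groups,
            "kind": kind,
            "pair_id": pair_id if pair_id is not None else pd.NA,
        }
    )
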