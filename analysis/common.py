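"""Shared setup for the numbered analysis drivers.

Every driver rebuilds the same seeded cohort (deterministic, ~1 s) so each
can be run independently; large matrices go to scratch/, summary tables to
results/.
"""

from __future__ import annotations

import os
from functools import lru_cache

from lnchet import preprocess
from lnchet.simulate import SimConfig, generate_cohort, generate_population_pairs

SEED = 7
REPO = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
RESULTS = os.path.join(REPO, "results")
SCRATCH = os.path.join(REPO, "scratch")


def ensure_dirs() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    os.makedirs(SCRATCH, exist_ok=True)


@lru_cache(maxsize=1)
def cohort():
    """(config, tpm, metadata, annotation, truth) at the default study scale."""
    cfg = SimConfig(seed=SEED)
    return (cfg, *generate_cohort(cfg))


@lru_cache(maxsize=1)
def population():
    cfg, m, meta, _annot, truth = cohort()
    return generate_population_pairs(m, meta, truth, top_frac=0.25)


@lru_cache(maxsize=1)
def processed():
    """(logged, selected genes, retained cells, z-scores)."""
    _cfg, m, meta, _annot, _truth = cohort()
    logged = preprocess.log_transform(m)
    genes = preprocess.select_genes(logged, meta)
    cells = preprocess.select_cells(logged, genes)
    z = preprocess.zscore(logged.subset(features=genes, samples=cells))
    return logged, genes, cells, z
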