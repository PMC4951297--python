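"""Expression filtering and normalization.

The workflow on TPM input: log2(TPM+1) transform; keep genes that are
abundant either globally (mean log2(TPM+1) > 2 across all single cells) or in
at least one tumor (group mean > 4); keep cells detecting at least half of
the retained genes; then per-gene z-scoring so expression is relative across
cells.  Both thresholds use strict inequality; "detected" means TPM > 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import (
    LOG2_TPM1,
    SINGLE_CELL,
    TPM,
    ZSCORE,
    ExpressionMatrix,
    samples_of_kind,
)

logger = logging.getLogger(__name__)


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """TPM -> log2(TPM + 1), feature/sample ids unchanged."""
    if m.space != TPM:
        raise ValueError(f"log_transform expects TPM input, got {m.space}")
    arr = m.values.to_numpy()
    if arr.size and arr.min() < 0:
        r, c = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative TPM at feature {m.values.index[r]!r}, sample {m.values.columns[c]!r}"
        )
    return ExpressionMatrix(np.log2(m.values + 1.0), LOG2_TPM1)


def select_genes(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    thr_all: float = 2.0,
    thr_group: float = 4.0,
    kinds: tuple[str, ...] = (SINGLE_CELL,),
) -> list[str]:
    """Two-tier abundance filter on log2(TPM+1).

    A gene passes if its mean over all considered cells exceeds ``thr_all``
    (strictly), or its mean within at least one group exceeds ``thr_group``.
    By default only single cells enter the averages; ``kinds`` widens that.
    Input order is preserved.
    """
    if m.space != LOG2_TPM1:
        raise ValueError("select_genes expects log2(TPM+1) input")
    samples = [s for k in kinds for s in samples_of_kind(meta, k)]
    sub = m.values[[s for s in m.sample_ids if s in set(samples)]]
    group = meta.set_index("sample_id").loc[sub.columns, "group"]
    keep = sub.mean(axis=1) > thr_all
    group_means = sub.T.groupby(group.values).mean().T
    keep |= (group_means > thr_group).any(axis=1)
    selected = list(m.values.index[keep])
    if not selected:
        logger.warning("gene filter removed every gene")
    return selected


def select_cells(
    m: ExpressionMatrix, genes: list[str], min_frac: float = 0.5
) -> list[str]:
    """Cells detecting at least ``min_frac`` of the selected genes.

    Detection is log2(TPM+1) > 0, i.e. TPM > 0; the bound is inclusive
    ("at least half").
    """
    if m.space != LOG2_TPM1:
        raise ValueError("select_cells expects log2(TPM+1) input")
    missing = set(genes) - set(m.feature_ids)
    if missing:
        raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
    sub = m.values.loc[genes]
    n_detected = (sub > 0).sum(axis=0)
    return list(m.values.columns[n_detected >= min_frac * len(genes)])


def zscore(
    m: ExpressionMatrix, ddof: int = 1, drop_constant: bool = True
) -> ExpressionMatrix:
    """Per-gene standardization: (v - mean) / sd over the included samples.

    Sample standard deviation (``ddof=1``) by default.  Constant genes have
    no defined z-score and are dropped (logged) rather than propagating NaN.
    """
    if m.space != LOG2_TPM1:
        raise ValueError("zscore expects log2(TPM+1) input")
    if m.shape[1] < 2:
        raise ValueError("zscore needs at least 2 samples")
    mean = m.values.mean(axis=1)
    sd = m.values.std(axis=1, ddof=ddof)
    constant = sd == 0
    if constant.any():
        if not drop_constant:
            raise ValueError(f"{int(constant.sum())} constant genes; cannot z-score")
        logger.info("dropping %d constant genes before z-scoring", int(constant.sum()))
    vals = m.values.loc[~constant]
    z = vals.sub(mean[~constant], axis=0).div(sd[~constant], axis=0)
    return ExpressionMatrix(z, ZSCORE)
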