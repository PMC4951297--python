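"""Within-gene splice-variant usage across single cells.

Relative abundance of each transcript within its gene per cell, selection of
genes with many annotated variants, dominant-variant calls, per-transcript
detection frequencies, per-cell variant counts, and pairwise co-expression /
mutual-exclusivity of variants (phi coefficient on detection indicators).
Detection means TPM > 0; zero-TPM variants never enter the abundance table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

ABUNDANCE_COLUMNS = ("gene_id", "transcript_id", "cell_id", "tpm", "rel_abund")


def relative_abundance(
    tx: ExpressionMatrix, g2t: pd.DataFrame, cells: list[str] | None = None
) -> pd.DataFrame:
    """Long-format table of within-gene relative transcript abundances.

    rel_abund(t, c) = tpm(t, c) / sum over the gene's transcripts in cell c,
    defined only where that denominator is positive.  Variants with zero TPM
    are filtered out.
    """
    if g2t["transcript_id"].duplicated().any():
        dup = g2t.loc[g2t["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise ValueError(f"transcript {dup!r} mapped to more than one gene")
    cells = list(cells) if cells is not None else tx.sample_ids
    present = g2t[g2t["transcript_id"].isin(tx.feature_ids)]
    records = []
    for gene, sub in present.groupby("gene_id", sort=True):
        tx_ids = list(sub["transcript_id"])
        block = tx.values.loc[tx_ids, cells]
        total = block.sum(axis=0)
        for cell in block.columns[total > 0]:
            col = block[cell]
            denom = total[cell]
            for t in tx_ids:
                v = col[t]
                if v > 0:
                    records.append((gene, t, cell, float(v), float(v / denom)))
    return pd.DataFrame(records, columns=list(ABUNDANCE_COLUMNS))


def select_multivariant_genes(g2t: pd.DataFrame, min_variants: int = 10) -> list[str]:
    """Genes whose annotated transcript count is at least ``min_variants``."""
    counts = g2t.groupby("gene_id", sort=False)["transcript_id"].nunique()
    return list(counts.index[counts >= min_variants])


@dataclass
class DominanceSummary:
    per_cell: pd.DataFrame  # gene_id, cell_id, dominant transcript (or NA)
    per_gene: pd.DataFrame  # gene_id, transcript_id, n_cells_dominant
    n_dominant_variants: pd.Series  # gene -> distinct dominant transcript count


def dominant_variants(tab: pd.DataFrame, threshold: float = 0.5) -> DominanceSummary:
    """Identify, per (gene, cell), the variant exceeding the dominance threshold.

    With the default threshold of 0.5 (strict), at most one transcript can
    dominate in a given cell.  A transcript is "a dominant variant" of a gene
    if it dominates in at least one cell.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    cell_rows, gene_counts = [], {}
    for (gene, cell), sub in tab.groupby(["gene_id", "cell_id"], sort=True):
        over = sub[sub["rel_abund"] > threshold]
        if threshold >= 0.5 and len(over) > 1:  # unreachable by pigeonhole
            raise AssertionError("multiple dominant variants above 0.5")
        dom = over["transcript_id"].iloc[0] if len(over) else pd.NA
        cell_rows.append((gene, cell, dom))
        if not pd.isna(dom):
            gene_counts[(gene, dom)] = gene_counts.get((gene, dom), 0) + 1
    per_cell = pd.DataFrame(cell_rows, columns=["gene_id", "cell_id", "dominant"])
    per_gene = pd.DataFrame(
        [(g, t, n) for (g, t), n in sorted(gene_counts.items())],
        columns=["gene_id", "transcript_id", "n_cells_dominant"],
    )
    n_dom = per_gene.groupby("gene_id")["transcript_id"].nunique()
    genes = per_cell["gene_id"].unique()
    n_dom = n_dom.reindex(genes, fill_value=0).astype(int)
    return DominanceSummary(per_cell, per_gene, n_dom)


def variant_frequency(tab: pd.DataFrame) -> pd.Series:
    """Per transcript, the number of cells in which it is detected."""
    return tab.groupby("transcript_id", sort=True)["cell_id"].nunique()


def variants_per_cell(
    tab: pd.DataFrame, gene: str, cells: list[str] | None = None
) -> pd.Series:
    """Per cell, the number of detected transcripts of one gene (0 allowed)."""
    if gene not in set(tab["gene_id"]):
        raise KeyError(f"gene {gene!r} not in abundance table")
    sub = tab[tab["gene_id"] == gene]
    counts = sub.groupby("cell_id")["transcript_id"].nunique()
    if cells is not None:
        counts = counts.reindex(cells, fill_value=0).astype(int)
    return counts


def _phi(x: np.ndarray, y: np.ndarray) -> float:
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    d = int(np.sum(~x & ~y))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return np.nan
    return (a * d - b * c) / math.sqrt(denom)


def variant_association(
    tab: pd.DataFrame,
    gene: str,
    method: str = "phi",
) -> pd.DataFrame:
    """Pairwise association of a gene's variants across expressing cells.

    Default: phi coefficient of the detection indicators over the cells in
    which the gene is expressed (+1 joint presence, -1 mutual exclusivity).
    ``method="pearson"`` correlates relative abundances instead.  Pairs with
    a constant indicator are NaN; genes expressed in fewer than 3 cells give
    an all-NaN matrix with a warning.
    """
    if method not in ("phi", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    sub = tab[tab["gene_id"] == gene]
    if sub.empty:
        raise KeyError(f"gene {gene!r} not in abundance table")
    wide = sub.pivot_table(
        index="transcript_id", columns="cell_id", values="rel_abund", fill_value=0.0
    )
    if wide.shape[0] < 2:
        raise ValueError(f"gene {gene!r} has fewer than 2 detected transcripts")
    n_tx = wide.shape[0]
    out = pd.DataFrame(np.eye(n_tx), index=wide.index, columns=wide.index)
    if wide.shape[1] < 3:
        warnings.warn(f"gene {gene!r} expressed in < 3 cells; associations undefined")
        out[:] = np.nan
        return out
    det = wide.to_numpy() > 0
    vals = wide.to_numpy()
    for i in range(n_tx):
        for j in range(i + 1, n_tx):
            if method == "phi":
                r = _phi(det[i], det[j])
            else:
                with np.errstate(invalid="ignore"):
                    r = float(np.corrcoef(vals[i], vals[j])[0, 1])
            out.iat[i, j] = out.iat[j, i] = r
    return out
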