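"""Core in-memory containers for expression data.

The central object is :class:`ExpressionMatrix`, a features x samples table of
nonnegative abundances carrying an explicit *space* tag so downstream code can
refuse to, e.g., z-score raw TPM or log-transform twice.  Sample metadata and
gene annotation are plain :class:`pandas.DataFrame` objects with a fixed column
contract, validated by the helpers below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised value spaces, in the order the pipeline produces them.
TPM = "TPM"
LOG2_TPM1 = "LOG2_TPM1"
ZSCORE = "ZSCORE"
SPACES = (TPM, LOG2_TPM1, ZSCORE)

#: Recognised sample kinds.
SINGLE_CELL = "single_cell"
POPULATION_CONTROL = "population_control"
GSC_CULTURE = "gsc_culture"
DGC_CULTURE = "dgc_culture"
SAMPLE_KINDS = (SINGLE_CELL, POPULATION_CONTROL, GSC_CULTURE, DGC_CULTURE)

METADATA_COLUMNS = ("sample_id", "group", "kind", "pair_id")


@dataclass
class ExpressionMatrix:
    """Features x samples abundance matrix with a value-space tag.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.
    space
        One of ``"TPM"``, ``"LOG2_TPM1"`` or ``"ZSCORE"``.
    """

    values: pd.DataFrame
    space: str = TPM

    def __post_init__(self) -> None:
        if self.space not in SPACES:
            raise ValueError(f"unknown expression space {self.space!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dupes[:5])}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dupes[:5])}")
        if self.space in (TPM, LOG2_TPM1):
            arr = self.values.to_numpy()
            if arr.size and np.nanmin(arr) < 0:
                r, c = np.argwhere(self.values.to_numpy() < 0)[0]
                raise ValueError(
                    f"negative value in {self.space} matrix at "
                    f"feature {self.values.index[r]!r}, sample {self.values.columns[c]!r}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, features=None, samples=None) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given feature/sample ids."""
        vals = self.values
        if features is not None:
            missing = set(features) - set(vals.index)
            if missing:
                raise KeyError(f"unknown features: {sorted(missing)[:5]}")
            vals = vals.loc[list(features)]
        if samples is not None:
            missing = set(samples) - set(vals.columns)
            if missing:
                raise KeyError(f"unknown samples: {sorted(missing)[:5]}")
            vals = vals[list(samples)]
        return ExpressionMatrix(vals, self.space)


def validate_metadata(meta: pd.DataFrame, matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Check the sample-metadata contract; returns the frame unchanged.

    Required columns: sample_id, group, kind, pair_id (pair_id may be empty /
    NA for unpaired samples).  If *matrix* is given, every sample in it must
    have a metadata row.
    """
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    bad_kinds = set(meta["kind"]) - set(SAMPLE_KINDS)
    if bad_kinds:
        raise ValueError(f"unknown sample kinds: {sorted(bad_kinds)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    if matrix is not None:
        missing = set(matrix.sample_ids) - set(meta["sample_id"])
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
    # paired GSC/DGC samples must share a group
    paired = meta.dropna(subset=["pair_id"])
    paired = paired[paired["pair_id"].astype(str) != ""]
    for pid, grp in paired.groupby("pair_id"):
        if grp["group"].nunique() > 1:
            raise ValueError(f"pair {pid!r} spans multiple groups")
    return meta


def samples_of_kind(meta: pd.DataFrame, kind: str) -> list[str]:
    """Sample ids of the given kind, in metadata order."""
    if kind not in SAMPLE_KINDS:
        raise ValueError(f"unknown sample kind {kind!r}")
    return list(meta.loc[meta["kind"] == kind, "sample_id"])


def group_of(meta: pd.DataFrame) -> pd.Series:
    """sample_id -> group mapping as a Series."""
    return meta.set_index("sample_id")["group"]


@dataclass
class GeneAnnotation:
    """Gene biotypes plus an optional gene -> transcripts map."""

    table: pd.DataFrame  # columns: gene_id, biotype
    gene_to_transcripts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "transcript_id"])
    )

    def __post_init__(self) -> None:
        if not {"gene_id", "biotype"} <= set(self.table.columns):
            raise ValueError("annotation table needs gene_id and biotype columns")
        g2t = self.gene_to_transcripts
        if len(g2t) and g2t["transcript_id"].duplicated().any():
            dup = g2t.loc[g2t["transcript_id"].duplicated(), "transcript_id"].iloc[0]
            raise ValueError(f"transcript {dup!r} mapped to more than one gene")

    def genes_of_biotype(self, biotype: str) -> list[str]:
        return list(self.table.loc[self.table["biotype"] == biotype, "gene_id"])
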