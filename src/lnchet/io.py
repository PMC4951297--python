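"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as TSV (first column = feature id, remaining
columns = samples) or as an MTX triplet (matrix.mtx + features.tsv +
barcodes.tsv, via :mod:`scipy.io`).  Gene sets use the GMT convention:
one set per line, tab-separated, ``name<TAB>description<TAB>member...``.
"""

from __future__ import annotations

import os

import pandas as pd
import scipy.io
import scipy.sparse

from .matrix import ExpressionMatrix, validate_metadata


def read_expression_tsv(path: str, space: str = "TPM") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, space)


def write_expression_tsv(m: ExpressionMatrix, path: str, feature_col: str = "feature_id") -> None:
    df = m.values.copy()
    df.index.name = feature_col
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_expression_mtx(dirpath: str, space: str = "TPM") -> ExpressionMatrix:
    mat = scipy.io.mmread(os.path.join(dirpath, "matrix.mtx"))
    features = pd.read_csv(os.path.join(dirpath, "features.tsv"), sep="\t", header=None)[0]
    barcodes = pd.read_csv(os.path.join(dirpath, "barcodes.tsv"), sep="\t", header=None)[0]
    df = pd.DataFrame(
        scipy.sparse.coo_matrix(mat).toarray(),
        index=features.astype(str),
        columns=barcodes.astype(str),
    )
    return ExpressionMatrix(df, space)


def write_expression_mtx(m: ExpressionMatrix, dirpath: str) -> None:
    os.makedirs(dirpath, exist_ok=True)
    sp = scipy.sparse.csr_matrix(m.values.to_numpy())
    scipy.io.mmwrite(os.path.join(dirpath, "matrix.mtx"), sp)
    pd.Series(m.feature_ids).to_csv(
        os.path.join(dirpath, "features.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(m.sample_ids).to_csv(
        os.path.join(dirpath, "barcodes.tsv"), sep="\t", index=False, header=False
    )


def read_metadata_tsv(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    meta["pair_id"] = meta["pair_id"].replace("", pd.NA)
    return validate_metadata(meta)


def write_metadata_tsv(meta: pd.DataFrame, path: str) -> None:
    validate_metadata(meta)
    meta.to_csv(path, sep="\t", index=False, na_rep="")


def read_gene_map_tsv(path: str) -> pd.DataFrame:
    """Gene -> transcript map with columns gene_id, transcript_id."""
    g2t = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "transcript_id"} <= set(g2t.columns):
        raise ValueError("gene map needs gene_id and transcript_id columns")
    return g2t


def write_gene_map_tsv(g2t: pd.DataFrame, path: str) -> None:
    g2t.to_csv(path, sep="\t", index=False)


def read_gmt(path: str) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: member list}; descriptions dropped."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, _desc, *members = parts
            sets[name] = [m for m in members if m]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
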