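"""Synthetic single-cell TPM cohorts with planted heterogeneity structure.

The generator emulates the statistical shape of a multi-tumor single-cell
RNA-seq study quantified in TPM: several tumors (groups) of single cells, a
lncRNA / protein-coding gene partition, logistic dropout, tumor-of-origin mean
shifts, coexpressed gene modules driven by per-cell latent activities, a
latent stemness gradient acting on a planted signature gene set,
subtype-specific shifts on planted classifier gene sets (with optional hybrid
cells carrying a half-strength secondary subtype), matched stem-like (GSC) and
differentiated (DGC) population samples built from the extremes of the
stemness gradient, and per-gene splice-variant proportions drawn from a
Dirichlet.

Expression model, per gene g and cell c, on the log2 scale:

    mu(g, c) = baseline(g) + groupshift(g, group(c))
               + module_shift * activity(module(g), c)
               + stemness_effect * latent(c)          [signature genes]
               + subtype effect terms                 [classifier genes]

    TPM(g, c) = max(2 ** (mu + noise) - 1, 0), then zeroed with probability
                1 - sigmoid(dropout_steepness * (mu - dropout_midpoint)).

All randomness flows from one seed through named substreams so each component
is independently reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import (
    DGC_CULTURE,
    GSC_CULTURE,
    SINGLE_CELL,
    ExpressionMatrix,
    GeneAnnotation,
    TPM,
)

SUBTYPES = ("PN", "N", "MES", "CL")

# substream labels -> fixed spawn order off the master SeedSequence
_STREAMS = ("baseline", "noise", "dropout", "dirichlet", "latent", "aux")


@dataclass
class SimConfig:
    """All knobs of the cohort generator.

    Defaults mirror the scale of a five-tumor single-cell study: 5 groups of
    40 cells, ~2,000 lncRNAs plus ~5,000 coding genes, a 31-gene stemness
    signature, four 8-gene subtype classifier sets, and 31 multi-variant
    genes with 12 annotated splice variants each.
    """

    n_groups: int = 5
    cells_per_group: int = 40
    n_lnc: int = 2000
    n_coding: int = 5000
    baseline_log_mean: float = 2.5
    baseline_log_sd: float = 1.5
    noise_sd: float = 0.5
    dropout_midpoint: float = 1.0
    dropout_steepness: float = 1.0
    group_shift_sd: float = 0.5
    n_modules: int = 4
    module_size: int = 50
    module_shift: float = 1.0
    stemness_set_size: int = 31
    stemness_effect: float = 2.0
    subtype_set_sizes: tuple[int, int, int, int] = (8, 8, 8, 8)
    subtype_effects: tuple[float, float, float, float] = (2.0, 2.0, 2.0, 2.0)
    hybrid_fraction: float = 0.2
    n_multivariant_genes: int = 31
    variants_per_gene: int = 12
    dirichlet_concentration: float = 0.3
    variant_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_groups",
            "cells_per_group",
            "n_lnc",
            "n_coding",
            "n_modules",
            "module_size",
            "stemness_set_size",
            "n_multivariant_genes",
            "variants_per_gene",
        ):
            v = getattr(self, name)
            if name == "n_coding":
                if v < 0:
                    raise ValueError(f"{name} must be >= 0, got {v}")
            elif not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive count, got {v!r}")
        if self.variants_per_gene < 2:
            raise ValueError("variants_per_gene must be >= 2")
        for name in ("module_shift", "stemness_effect", "group_shift_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(e < 0 for e in self.subtype_effects):
            raise ValueError("subtype effects must be >= 0")
        if any(s <= 0 for s in self.subtype_set_sizes):
            raise ValueError("subtype set sizes must be > 0")
        if self.dropout_steepness <= 0:
            raise ValueError("dropout_steepness must be > 0")
        if not 0 <= self.hybrid_fraction < 1:
            raise ValueError("hybrid_fraction must be in [0, 1)")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        needed = (
            self.stemness_set_size
            + sum(self.subtype_set_sizes)
            + self.n_multivariant_genes
        )
        if needed > self.n_lnc:
            raise ValueError(
                f"planted lncRNA sets need {needed} genes but n_lnc={self.n_lnc}"
            )

    def rng(self, stream: str) -> np.random.Generator:
        """Seeded generator for a named substream."""
        idx = _STREAMS.index(stream)
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[idx])


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator, keyed by gene/cell ids."""

    stemness_latent: pd.Series
    subtype_label: pd.Series
    secondary_label: pd.Series  # NA where the cell is pure
    group_of_origin: pd.Series
    module_membership: pd.Series  # gene -> module id, NA outside modules
    signature_genes: list[str] = field(default_factory=list)
    classifier_genes: dict = field(default_factory=dict)  # biotype -> {subtype: genes}
    variant_proportions: dict = field(default_factory=dict)  # gene -> DataFrame (variants x cells)


def _gene_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    lnc = [f"LNC{i:05d}" for i in range(config.n_lnc)]
    coding = [f"PC{i:05d}" for i in range(config.n_coding)]
    return lnc, coding


def _cell_ids(config: SimConfig) -> tuple[list[str], np.ndarray]:
    cells, group_idx = [], []
    for g in range(config.n_groups):
        for c in range(config.cells_per_group):
            cells.append(f"T{g + 1}_C{c + 1:03d}")
            group_idx.append(g)
    return cells, np.asarray(group_idx)


def generate_cohort(
    config: SimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GeneAnnotation, SyntheticTruth]:
    """Simulate the single-cell TPM matrix plus metadata, annotation, truth."""
    lnc, coding = _gene_ids(config)
    genes = lnc + coding
    n_genes, n_cells = len(genes), config.n_groups * config.cells_per_group
    cells, group_idx = _cell_ids(config)
    groups = [f"T{g + 1}" for g in range(config.n_groups)]

    rs = config.rng("baseline")
    baseline = rs.normal(config.baseline_log_mean, config.baseline_log_sd, n_genes)
    gshift = rs.normal(0.0, config.group_shift_sd, (n_genes, config.n_groups))

    # planted gene sets: disjoint, drawn from the lncRNA block (signature and
    # classifiers are lncRNA analyses); module genes drawn from everything left
    ra = config.rng("aux")
    lnc_pool = list(rs.permutation(config.n_lnc))
    signature = sorted(lnc_pool[: config.stemness_set_size])
    offset = config.stemness_set_size
    classifier: dict[str, dict[str, list[str]]] = {"lncRNA": {}}
    for s, size in zip(SUBTYPES, config.subtype_set_sizes):
        classifier["lncRNA"][s] = sorted(lnc_pool[offset : offset + size])
        offset += size
    multivariant_idx = sorted(lnc_pool[offset : offset + config.n_multivariant_genes])
    offset += config.n_multivariant_genes
    if config.n_coding:
        coding_pool = list(rs.permutation(config.n_coding))
        classifier["protein_coding"] = {}
        coff = 0
        for s, size in zip(SUBTYPES, config.subtype_set_sizes):
            classifier["protein_coding"][s] = sorted(
                config.n_lnc + i for i in coding_pool[coff : coff + size]
            )
            coff += size
    taken = set(signature)
    for bt in classifier.values():
        for idxs in bt.values():
            taken.update(idxs)
    # published signature / classifier sets are members of the retained
    # abundant library by construction; emulate that by drawing the planted
    # sets' baselines from the upper half of the baseline distribution
    planted = sorted(taken)
    baseline[planted] = config.baseline_log_mean + np.abs(
        ra.normal(0.0, config.baseline_log_sd, len(planted))
    )
    free = [i for i in range(n_genes) if i not in taken]
    module_members = {}
    pos = 0
    free = list(np.asarray(free)[ra.permutation(len(free))])
    for m in range(config.n_modules):
        module_members[m] = sorted(free[pos : pos + config.module_size])
        pos += config.module_size
        if len(module_members[m]) < config.module_size:
            raise ValueError("not enough genes for the requested modules")

    rl = config.rng("latent")
    latent = rl.uniform(0.0, 1.0, n_cells)
    primary = rl.integers(0, len(SUBTYPES), n_cells)
    is_hybrid = rl.uniform(size=n_cells) < config.hybrid_fraction
    secondary = np.where(
        is_hybrid, (primary + 1 + rl.integers(0, len(SUBTYPES) - 1, n_cells)) % 4, -1
    )
    activity = rl.normal(0.0, 1.0, (config.n_modules, n_cells))

    mu = baseline[:, None] + gshift[:, group_idx]
    for m, members in module_members.items():
        mu[members, :] += config.module_shift * activity[m][None, :]
    mu[signature, :] += config.stemness_effect * latent[None, :]
    for bt, sets in classifier.items():
        for s_i, s in enumerate(SUBTYPES):
            idxs = sets[s]
            eff = config.subtype_effects[s_i]
            mu[np.ix_(idxs, np.where(primary == s_i)[0])] += eff
            mu[np.ix_(idxs, np.where(secondary == s_i)[0])] += eff / 2.0

    rn = config.rng("noise")
    x = mu + rn.normal(0.0, config.noise_sd, (n_genes, n_cells))
    tpm = np.clip(np.exp2(x) - 1.0, 0.0, None)

    rd = config.rng("dropout")
    p_detect = 1.0 / (1.0 + np.exp(-config.dropout_steepness * (mu - config.dropout_midpoint)))
    tpm[rd.uniform(size=tpm.shape) >= p_detect] = 0.0

    matrix = ExpressionMatrix(pd.DataFrame(tpm, index=genes, columns=cells), TPM)
    meta = pd.DataFrame(
        {
            "sample_id": cells,
            "group": [groups[g] for g in group_idx],
            "kind": SINGLE_CELL,
            "pair_id": pd.NA,
        }
    )
    annot = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": genes,
                "biotype": ["lncRNA"] * config.n_lnc + ["protein_coding"] * config.n_coding,
            }
        )
    )
    gene_arr = np.asarray(genes)
    module_series = pd.Series(pd.NA, index=genes, dtype="object")
    for m, members in module_members.items():
        module_series.iloc[members] = m
    truth = SyntheticTruth(
        stemness_latent=pd.Series(latent, index=cells),
        subtype_label=pd.Series([SUBTYPES[p] for p in primary], index=cells),
        secondary_label=pd.Series(
            [SUBTYPES[s] if s >= 0 else pd.NA for s in secondary], index=cells
        ),
        group_of_origin=pd.Series([groups[g] for g in group_idx], index=cells),
        module_membership=module_series,
        signature_genes=list(gene_arr[signature]),
        classifier_genes={
            bt: {s: list(gene_arr[idxs]) for s, idxs in sets.items()}
            for bt, sets in classifier.items()
        },
    )
    truth.multivariant_genes = list(gene_arr[multivariant_idx])  # type: ignore[attr-defined]
    return matrix, meta, annot, truth


def generate_population_pairs(
    cohort: ExpressionMatrix,
    meta: pd.DataFrame,
    truth: SyntheticTruth,
    top_frac: float = 0.25,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Paired GSC/DGC population samples from the stemness extremes.

    Per group, the GSC sample is the per-gene mean TPM over the ``top_frac``
    cells with the highest stemness latent; the DGC sample averages the bottom
    ``top_frac``.  Metadata records the group as pair_id.
    """
    if not 0 < top_frac < 0.5:
        raise ValueError("top_frac must be in (0, 0.5)")
    cols, rows = {}, []
    for group in truth.group_of_origin.unique():
        cells = truth.group_of_origin.index[truth.group_of_origin == group]
        if len(cells) < 2.0 / top_frac:
            raise ValueError(
                f"group {group} has {len(cells)} cells; needs >= {2.0 / top_frac:.0f} "
                f"for top_frac={top_frac}"
            )
        n_sel = int(round(top_frac * len(cells)))
        order = truth.stemness_latent.loc[cells].sort_values(kind="stable")
        top, bottom = list(order.index[-n_sel:]), list(order.index[:n_sel])
        cols[f"{group}_GSC"] = cohort.values[top].mean(axis=1)
        cols[f"{group}_DGC"] = cohort.values[bottom].mean(axis=1)
        rows.append((f"{group}_GSC", group, GSC_CULTURE, group))
        rows.append((f"{group}_DGC", group, DGC_CULTURE, group))
    pop = ExpressionMatrix(pd.DataFrame(cols, index=cohort.feature_ids), TPM)
    pop_meta = pd.DataFrame(rows, columns=["sample_id", "group", "kind", "pair_id"])
    return pop, pop_meta


def generate_variant_profiles(
    config: SimConfig,
    gene_tpm: ExpressionMatrix | None = None,
    genes: list[str] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict]:
    """Split gene-level TPM across splice variants by per-cell Dirichlet draws.

    Returns the transcript-level TPM matrix, the gene -> transcript map, and
    the truth proportion vectors (gene -> variants x cells DataFrame, each
    column summing to 1).  Proportions drawn below ``variant_floor`` are set
    to exactly zero (variants without expression) and the survivors are
    renormalised, so transcript TPMs sum exactly to the gene TPM.
    """
    k = config.variants_per_gene
    if k < 2:
        raise ValueError("variants_per_gene must be >= 2")
    rng = config.rng("dirichlet")
    if gene_tpm is None:
        # self-contained gene-level simulation on the generator's own substream
        cells, _ = _cell_ids(config)
        if genes is None:
            genes = [f"MVG{i:04d}" for i in range(config.n_multivariant_genes)]
        base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, len(genes))
        x = base[:, None] + rng.normal(0.0, config.noise_sd, (len(genes), len(cells)))
        vals = np.clip(np.exp2(x) - 1.0, 0.0, None)
        p = 1.0 / (
            1.0
            + np.exp(-config.dropout_steepness * (base[:, None] - config.dropout_midpoint))
        )
        vals[rng.uniform(size=vals.shape) >= p] = 0.0
        gene_tpm = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=cells), TPM)
    else:
        if genes is None:
            genes = gene_tpm.feature_ids
        gene_tpm = gene_tpm.subset(features=genes)
        cells = gene_tpm.sample_ids

    tx_rows, tx_index, g2t_rows = [], [], []
    proportions: dict[str, pd.DataFrame] = {}
    alpha = np.full(k, config.dirichlet_concentration)
    for gene in genes:
        props = rng.dirichlet(alpha, size=len(cells)).T  # variants x cells
        props[props < config.variant_floor] = 0.0
        colsum = props.sum(axis=0)
        dead = colsum == 0
        if dead.any():  # extreme floor: keep the largest raw draw
            warnings.warn("variant floor removed all variants in some cells; keeping argmax")
            props[0, dead] = 1.0
            colsum = props.sum(axis=0)
        props /= colsum
        tx_ids = [f"{gene}:v{j + 1}" for j in range(k)]
        g2t_rows += [(gene, t) for t in tx_ids]
        tx_index += tx_ids
        tx_rows.append(props * gene_tpm.values.loc[gene].to_numpy()[None, :])
        proportions[gene] = pd.DataFrame(props, index=tx_ids, columns=cells)
    tx = ExpressionMatrix(
        pd.DataFrame(np.vstack(tx_rows), index=tx_index, columns=cells), TPM
    )
    g2t = pd.DataFrame(g2t_rows, columns=["gene_id", "transcript_id"])
    return tx, g2t, proportions
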