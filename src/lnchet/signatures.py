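"""Stemness signature derivation, signature scoring, and subtype calling.

The stemness signature is the set of genes significantly higher in stem-like
(GSC) than in matched differentiated (DGC) population cultures by a paired
t-test across tumor-derived pairs.  A cell's signature score is the mean
z-score of the signature genes minus the mean z-score of the full analysis
universe, so adding a per-cell constant to every gene cancels out.  The
spread of scores within one tumor (the stemness gradient) is compared
against size-matched random gene sets; subtype scores use the same scoring
with per-subtype classifier sets and an empirical cutoff from the upper
quantile of pooled random-set scores, allowing cells to pass several
subtypes (hybrid states) or none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .matrix import DGC_CULTURE, GSC_CULTURE, ZSCORE, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SignatureSet:
    name: str
    genes: list[str]
    direction: str = "up_in_gsc"
    stats: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")


def derive_stemness_signature(
    pop: ExpressionMatrix,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    per_pair_fold: bool = False,
) -> SignatureSet:
    """Genes up in GSC vs DGC by a paired t-test across culture pairs.

    One test per gene over the per-pair (GSC - DGC) differences; the
    signature keeps genes with p < alpha and a positive mean difference.
    Genes whose difference is identical across pairs (sd = 0) but positive
    are perfectly consistent: they are kept with p recorded as 0 and
    flagged.  ``per_pair_fold=True`` switches to the alternative reading
    requiring a positive difference in every single pair (on top of the
    test).
    """
    sub = meta[meta["kind"].isin([GSC_CULTURE, DGC_CULTURE])].dropna(subset=["pair_id"])
    pairs = []
    for pid, grp in sub.groupby("pair_id"):
        gsc = grp.loc[grp["kind"] == GSC_CULTURE, "sample_id"]
        dgc = grp.loc[grp["kind"] == DGC_CULTURE, "sample_id"]
        if len(gsc) == 1 and len(dgc) == 1:
            pairs.append((pid, gsc.iloc[0], dgc.iloc[0]))
    if len(pairs) < 2:
        raise ValueError(f"need >= 2 GSC/DGC pairs, found {len(pairs)}")
    diffs = pd.DataFrame(
        {pid: pop.values[g] - pop.values[d] for pid, g, d in pairs}
    )
    mean_diff = diffs.mean(axis=1)
    sd_diff = diffs.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = scipy.stats.ttest_rel(
            pop.values[[g for _, g, _ in pairs]].to_numpy(),
            pop.values[[d for _, _, d in pairs]].to_numpy(),
            axis=1,
        )
    pval = pd.Series(pval, index=pop.values.index)
    degenerate = (sd_diff == 0) & (mean_diff != 0)
    if degenerate.any():
        logger.info(
            "%d genes with identical nonzero difference in every pair (p set to 0)",
            int(degenerate.sum()),
        )
    pval[degenerate] = 0.0
    pval[(sd_diff == 0) & (mean_diff == 0)] = 1.0
    keep = (pval < alpha) & (mean_diff > 0)
    if per_pair_fold:
        keep &= (diffs > 0).all(axis=1)
    stats = pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "t": tstat,
            "p": pval,
            "q": multipletests(pval.fillna(1.0), method="fdr_bh")[1],
            "selected": keep,
        }
    )
    return SignatureSet("stemness", list(pop.values.index[keep]), "up_in_gsc", stats)


def signature_score(z: ExpressionMatrix, sig: SignatureSet) -> pd.Series:
    """Mean z of the signature genes minus the mean z of the universe, per cell."""
    if z.space != ZSCORE:
        raise ValueError("signature_score expects z-scored input")
    missing = [g for g in sig.genes if g not in set(z.feature_ids)]
    if missing:
        raise KeyError(f"signature genes missing from matrix: {missing[:10]}")
    return z.values.loc[sig.genes].mean(axis=0) - z.values.mean(axis=0)


def _random_sets(
    universe: list[str], size: int, n_random: int, rng: np.random.Generator
) -> list[list[str]]:
    uni = np.asarray(universe)
    return [list(uni[rng.choice(len(uni), size, replace=False)]) for _ in range(n_random)]


def gradient_significance(
    z: ExpressionMatrix,
    sig: SignatureSet,
    grouping: pd.Series,
    n_random: int = 100,
    seed: int | np.random.Generator = 0,
    universe: list[str] | None = None,
) -> pd.DataFrame:
    """Is the within-tumor spread of signature scores larger than random?

    Per group: SD of the per-cell signature scores, the mean SD over
    ``n_random`` size-matched random gene sets, and the empirical
    p = (1 + #{null SD >= observed}) / (1 + n_random).
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    universe = universe if universe is not None else z.feature_ids
    if len(universe) < 2 * len(sig.genes):
        logger.warning("universe smaller than twice the signature; nulls overlap heavily")
    grouping = grouping.reindex(z.sample_ids)
    scores = signature_score(z, sig)
    nulls = [
        signature_score(z, SignatureSet(f"null{i}", gs))
        for i, gs in enumerate(_random_sets(universe, len(sig.genes), n_random, rng))
    ]
    rows = []
    for group in grouping.dropna().unique():
        cells = grouping.index[grouping == group]
        if len(cells) < 3:
            raise ValueError(f"group {group} has fewer than 3 cells")
        obs = float(scores.loc[cells].std(ddof=1))
        null_sds = np.array([float(nv.loc[cells].std(ddof=1)) for nv in nulls])
        p = (1.0 + float((null_sds >= obs).sum())) / (1.0 + n_random)
        rows.append((group, obs, float(null_sds.mean()), p))
    return pd.DataFrame(rows, columns=["group", "sd_observed", "sd_random_mean", "p"])


def subtype_scores(z: ExpressionMatrix, classifiers: dict[str, SignatureSet]) -> pd.DataFrame:
    """One signature score per cell and subtype (cells x subtypes)."""
    return pd.DataFrame({name: signature_score(z, sig) for name, sig in classifiers.items()})


def subtype_cutoffs(
    z: ExpressionMatrix,
    classifiers: dict[str, SignatureSet],
    n_random: int = 100,
    q: float = 0.01,
    seed: int | np.random.Generator = 0,
    universe: list[str] | None = None,
    pooled: bool = True,
) -> pd.Series:
    """Empirical per-subtype score cutoffs from random gene sets.

    For each subtype, ``n_random`` size-matched random sets are scored in
    every cell; the cutoff is the (1 - q) quantile of the pooled
    n_random x n_cells null scores (or per-cell quantiles averaged, with
    ``pooled=False``).
    """
    if not 0.0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    universe = universe if universe is not None else z.feature_ids
    cutoffs = {}
    for name, sig in classifiers.items():
        null_scores = np.concatenate(
            [
                signature_score(z, SignatureSet(f"null{i}", gs)).to_numpy()
                for i, gs in enumerate(_random_sets(universe, len(sig.genes), n_random, rng))
            ]
        )
        if pooled:
            cutoffs[name] = float(np.quantile(null_scores, 1.0 - q))
        else:
            per_cell = null_scores.reshape(n_random, -1)
            cutoffs[name] = float(np.quantile(per_cell, 1.0 - q, axis=0).mean())
    return pd.Series(cutoffs)


@dataclass
class SubtypeCall:
    passing: pd.DataFrame  # cells x subtypes, boolean
    scores: pd.DataFrame  # cells x subtypes
    n_subtypes: pd.Series  # cells -> count of passing subtypes

    def top_label(self) -> pd.Series:
        """Top-scoring passing subtype per cell, NA where none pass."""
        lab = pd.Series(pd.NA, index=self.scores.index, dtype="object")
        any_pass = self.n_subtypes > 0
        if any_pass.any():
            masked = self.scores.where(self.passing)
            lab[any_pass] = masked[any_pass].idxmax(axis=1)
        return lab


def classify_cells(scores: pd.DataFrame, cutoffs: pd.Series) -> SubtypeCall:
    """A cell passes every subtype whose score strictly exceeds its cutoff."""
    missing = set(scores.columns) ^ set(cutoffs.index)
    if missing:
        raise ValueError(f"scores and cutoffs disagree on subtypes: {sorted(missing)}")
    passing = scores.gt(cutoffs, axis=1)
    return SubtypeCall(passing, scores, passing.sum(axis=1))


def classification_consistency(a: SubtypeCall, b: SubtypeCall) -> float:
    """Percent of cells whose top-scoring passing subtype agrees.

    Two unclassified calls for the same cell count as agreement.
    """
    if set(a.scores.index) != set(b.scores.index):
        raise ValueError("subtype calls cover different cell sets")
    la, lb = a.top_label(), b.top_label().reindex(a.scores.index)
    agree = (la == lb) | (la.isna() & lb.isna())
    return float(agree.mean() * 100.0)
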