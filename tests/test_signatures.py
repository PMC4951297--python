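"""Stemness signature derivation, scoring, gradient test, subtype calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from conftest import make_matrix, make_meta
from lnchet import preprocess, signatures
from lnchet.matrix import LOG2_TPM1, ZSCORE, ExpressionMatrix


def _pop_matrix(diffs: dict[str, list[float]], base: float = 5.0):
    """Population matrix with 3 GSC/DGC pairs and specified per-gene diffs."""
    genes = list(diffs)
    cols, names, rows = [], [], []
    for i, pid in enumerate(("P1", "P2", "P3")):
        dgc = np.full(len(genes), base) + 0.1 * i
        gsc = dgc + np.array([diffs[g][i] for g in genes])
        cols += [gsc, dgc]
        names += [f"{pid}_GSC", f"{pid}_DGC"]
        rows += [
            (f"{pid}_GSC", pid, "gsc_culture", pid),
            (f"{pid}_DGC", pid, "dgc_culture", pid),
        ]
    m = ExpressionMatrix(
        pd.DataFrame(np.column_stack(cols), index=genes, columns=names), LOG2_TPM1
    )
    meta = pd.DataFrame(rows, columns=["sample_id", "group", "kind", "pair_id"])
    return m, meta


class TestDeriveStemnessSignature:
    def test_flat_gene_excluded_consistent_gene_included(self):
        m, meta = _pop_matrix(
            {
                "flat": [0.0, 0.0, 0.0],
                "consistent_up": [1.0, 1.0, 1.0],  # sd=0, mean>0 -> kept, p=0
                "noisy_up": [2.0, 1.5, 2.5],
                "down": [-2.0, -1.5, -2.5],
            }
        )
        sig = signatures.derive_stemness_signature(m, meta)
        assert "flat" not in sig.genes
        assert "consistent_up" in sig.genes
        assert sig.stats.loc["consistent_up", "p"] == 0.0
        assert "noisy_up" in sig.genes
        assert "down" not in sig.genes  # significant but wrong direction

    def test_fewer_than_two_pairs_rejected(self):
        m, meta = _pop_matrix({"g": [1.0, 1.0, 1.0]})
        meta = meta[meta["pair_id"] == "P1"]
        with pytest.raises(ValueError, match="pairs"):
            signatures.derive_stemness_signature(m, meta[meta["pair_id"] == "P1"])

    def test_recovers_planted_signature(self, small_cohort, population_pairs):
        _cfg, _m, _meta, _annot, truth = small_cohort
        pop, pop_meta = population_pairs
        sig = signatures.derive_stemness_signature(
            preprocess.log_transform(pop), pop_meta
        )
        planted = set(truth.signature_genes)
        recall = len(set(sig.genes) & planted) / len(planted)
        assert recall >= 0.9
        n_other = len(pop.feature_ids) - len(planted)
        assert len(set(sig.genes) - planted) <= 0.05 * n_other * 2


def _zmat(arr, genes=None, cells=None):
    genes = genes or [f"g{i}" for i in range(np.asarray(arr).shape[0])]
    cells = cells or [f"c{i}" for i in range(np.asarray(arr).shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(arr, dtype=float), index=genes, columns=cells), ZSCORE
    )


class TestSignatureScore:
    def test_signature_equal_to_universe_scores_zero(self):
        z = _zmat(np.random.default_rng(0).normal(0, 1, (6, 4)))
        sig = signatures.SignatureSet("all", z.feature_ids)
        np.testing.assert_allclose(signatures.signature_score(z, sig), 0.0, atol=1e-12)

    def test_hand_computed_toy(self):
        # universe of 4 genes, signature = first 2:
        # cell c0: mean(1,2) - mean(1,2,3,6) = 1.5 - 3 = -1.5
        z = _zmat([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0], [6.0, 0.0]])
        sig = signatures.SignatureSet("s", ["g0", "g1"])
        scores = signatures.signature_score(z, sig)
        assert scores["c0"] == pytest.approx(-1.5)
        assert scores["c1"] == pytest.approx(0.0)

    def test_invariant_to_per_cell_constant(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(0, 1, (10, 6))
        z1 = _zmat(arr)
        z2 = _zmat(arr + rng.normal(0, 3, 6)[None, :])
        sig = signatures.SignatureSet("s", ["g0", "g3", "g7"])
        np.testing.assert_allclose(
            signatures.signature_score(z1, sig),
            signatures.signature_score(z2, sig),
            atol=1e-10,
        )

    def test_missing_genes_reported(self):
        z = _zmat(np.zeros((3, 3)))
        with pytest.raises(KeyError, match="missing"):
            signatures.signature_score(z, signatures.SignatureSet("s", ["nope"]))


class TestGradientSignificance:
    def test_planted_gradient_detected(self, small_cohort, processed):
        _cfg, _m, meta, _annot, truth = small_cohort
        *_rest, z = processed
        present = [g for g in truth.signature_genes if g in set(z.feature_ids)]
        sig = signatures.SignatureSet("stemness", present)
        out = signatures.gradient_significance(
            z, sig, meta.set_index("sample_id")["group"], n_random=100, seed=2
        )
        assert (out["p"] <= 0.05).all()
        assert (out["sd_observed"] > out["sd_random_mean"]).all()

    def test_zero_random_sets_rejected(self, processed):
        *_rest, z = processed
        sig = signatures.SignatureSet("s", z.feature_ids[:5])
        with pytest.raises(ValueError):
            signatures.gradient_significance(
                z, sig, pd.Series("A", index=z.sample_ids), n_random=0
            )

    def test_empirical_p_never_zero(self, processed):
        *_rest, z = processed
        sig = signatures.SignatureSet("s", z.feature_ids[:5])
        out = signatures.gradient_significance(
            z, sig, pd.Series("A", index=z.sample_ids), n_random=50, seed=3
        )
        assert (out["p"] >= 1.0 / 51).all()


class TestSubtypeCalls:
    def test_cutoff_guards(self, processed):
        *_rest, z = processed
        cls = {"PN": signatures.SignatureSet("PN", z.feature_ids[:4])}
        for bad_q in (0.0, 0.5, 0.9):
            with pytest.raises(ValueError):
                signatures.subtype_cutoffs(z, cls, q=bad_q)

    def test_degenerate_zero_matrix(self):
        z = _zmat(np.zeros((10, 5)))
        cls = {"PN": signatures.SignatureSet("PN", ["g0", "g1"])}
        cut = signatures.subtype_cutoffs(z, cls, n_random=20, q=0.01, seed=4)
        assert cut["PN"] == 0.0
        call = signatures.classify_cells(signatures.subtype_scores(z, cls), cut)
        assert (call.n_subtypes == 0).all()  # no strict exceedance

    def test_extreme_cells_pass_all_or_none(self):
        scores = pd.DataFrame(
            {"PN": [5.0, -5.0], "N": [5.0, -5.0], "MES": [5.0, -5.0], "CL": [5.0, -5.0]},
            index=["hot", "cold"],
        )
        cut = pd.Series({"PN": 0.1, "N": 0.1, "MES": 0.1, "CL": 0.1})
        call = signatures.classify_cells(scores, cut)
        assert call.n_subtypes["hot"] == 4
        assert call.n_subtypes["cold"] == 0
        assert pd.isna(call.top_label()["cold"])

    def test_stemness_score_tracks_latent(self, small_cohort, processed):
        _cfg, _m, _meta, _annot, truth = small_cohort
        *_rest, z = processed
        present = [g for g in truth.signature_genes if g in set(z.feature_ids)]
        scores = signatures.signature_score(z, signatures.SignatureSet("s", present))
        rho = spearmanr(scores, truth.stemness_latent.loc[scores.index])[0]
        assert rho > 0.8


class TestConsistency:
    def _call(self, labels, all_pass=True):
        cells = [f"c{i}" for i in range(len(labels))]
        names = ["PN", "N", "MES", "CL"]
        scores = pd.DataFrame(0.0, index=cells, columns=names)
        passing = pd.DataFrame(False, index=cells, columns=names)
        for c, lab in zip(cells, labels):
            if lab is not None:
                scores.loc[c, lab] = 1.0
                passing.loc[c, lab] = True
        return signatures.SubtypeCall(passing, scores, passing.sum(axis=1))

    def test_self_consistency_is_100(self):
        a = self._call(["PN", "MES", None, "CL"])
        assert signatures.classification_consistency(a, a) == 100.0

    def test_complete_permutation_is_0(self):
        a = self._call(["PN", "N", "MES", "CL"])
        b = self._call(["N", "MES", "CL", "PN"])
        assert signatures.classification_consistency(a, b) == 0.0

    def test_seven_of_ten_is_70(self):
        la = ["PN"] * 10
        lb = ["PN"] * 7 + ["MES"] * 3
        assert signatures.classification_consistency(self._call(la), self._call(lb)) == 70.0

    def test_disjoint_cells_rejected(self):
        a = self._call(["PN"])
        b = self._call(["PN", "N"])
        with pytest.raises(ValueError):
            signatures.classification_consistency(a, b)
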