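"""Splice-variant relative abundance, dominance, frequency, association."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from lnchet import splicing
from lnchet.simulate import SimConfig, generate_variant_profiles


def _toy_table():
    """Two genes, three cells; hand-checkable abundances."""
    tx = make_matrix(
        np.array(
            [
                [10.0, 0.0, 4.0],  # gA.t1
                [30.0, 0.0, 4.0],  # gA.t2
                [5.0, 7.0, 0.0],  # gB.t1
            ]
        ),
        features=["gA.t1", "gA.t2", "gB.t1"],
        samples=["c1", "c2", "c3"],
    )
    g2t = pd.DataFrame(
        {
            "gene_id": ["gA", "gA", "gB"],
            "transcript_id": ["gA.t1", "gA.t2", "gB.t1"],
        }
    )
    return tx, g2t


class TestRelativeAbundance:
    def test_hand_computed_ratios(self):
        tx, g2t = _toy_table()
        tab = splicing.relative_abundance(tx, g2t)
        r = tab.set_index(["transcript_id", "cell_id"])["rel_abund"]
        assert r[("gA.t1", "c1")] == pytest.approx(0.25)
        assert r[("gA.t2", "c1")] == pytest.approx(0.75)
        assert r[("gB.t1", "c1")] == pytest.approx(1.0)  # single expressed variant
        # gene gA undetected in c2 -> no records at all
        assert not ((tab["gene_id"] == "gA") & (tab["cell_id"] == "c2")).any()
        # zero-tpm variants never appear
        assert (tab["tpm"] > 0).all()

    def test_sum_to_one_per_gene_cell(self):
        tx, g2t = _toy_table()
        tab = splicing.relative_abundance(tx, g2t)
        sums = tab.groupby(["gene_id", "cell_id"])["rel_abund"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_ambiguous_transcript_rejected(self):
        tx, g2t = _toy_table()
        bad = pd.concat(
            [g2t, pd.DataFrame({"gene_id": ["gB"], "transcript_id": ["gA.t1"]})]
        )
        with pytest.raises(ValueError, match="more than one gene"):
            splicing.relative_abundance(tx, bad)


class TestMultivariantSelection:
    def test_inclusive_threshold(self):
        g2t = pd.DataFrame(
            {
                "gene_id": ["a"] * 10 + ["b"] * 9 + ["c"] * 11,
                "transcript_id": [f"t{i}" for i in range(30)],
            }
        )
        assert splicing.select_multivariant_genes(g2t, 10) == ["a", "c"]

    def test_recovers_planted_counts(self):
        cfg = SimConfig(
            n_groups=1, cells_per_group=10, n_lnc=100, n_coding=0,
            stemness_set_size=5, subtype_set_sizes=(2, 2, 2, 2),
            n_multivariant_genes=6, variants_per_gene=10, seed=3,
        )
        _tx, g2t, _props = generate_variant_profiles(cfg)
        assert len(splicing.select_multivariant_genes(g2t, 10)) == 6
        assert splicing.select_multivariant_genes(g2t, 11) == []


class TestDominance:
    def test_strict_majority_required(self):
        tab = pd.DataFrame(
            {
                "gene_id": ["g"] * 4,
                "transcript_id": ["t1", "t2", "t1", "t2"],
                "cell_id": ["c1", "c1", "c2", "c2"],
                "tpm": [6.0, 4.0, 5.0, 5.0],
                "rel_abund": [0.6, 0.4, 0.5, 0.5],
            }
        )
        out = splicing.dominant_variants(tab)
        per_cell = out.per_cell.set_index("cell_id")["dominant"]
        assert per_cell["c1"] == "t1"
        assert pd.isna(per_cell["c2"])  # 0.5 is not > 0.5
        assert out.n_dominant_variants["g"] == 1

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.0, 1.5])
    def test_threshold_bounds(self, bad):
        with pytest.raises(ValueError):
            splicing.dominant_variants(pd.DataFrame(columns=list(splicing.ABUNDANCE_COLUMNS)), bad)

    def test_at_most_one_dominant_per_cell(self):
        cfg = SimConfig(
            n_groups=1, cells_per_group=30, n_lnc=100, n_coding=0,
            stemness_set_size=5, subtype_set_sizes=(2, 2, 2, 2),
            n_multivariant_genes=5, variants_per_gene=10,
            dirichlet_concentration=0.2, seed=9,
        )
        tx, g2t, _ = generate_variant_profiles(cfg)
        tab = splicing.relative_abundance(tx, g2t)
        out = splicing.dominant_variants(tab)
        # pigeonhole: one row per (gene, cell)
        assert not out.per_cell.duplicated(["gene_id", "cell_id"]).any()


class TestFrequencyAndCounts:
    def test_hand_tally(self):
        tx, g2t = _toy_table()
        tab = splicing.relative_abundance(tx, g2t)
        freq = splicing.variant_frequency(tab)
        assert freq["gA.t1"] == 2  # c1 and c3
        assert freq["gB.t1"] == 2  # c1 and c2

    def test_variants_per_cell_with_zeros(self):
        tx, g2t = _toy_table()
        tab = splicing.relative_abundance(tx, g2t)
        counts = splicing.variants_per_cell(tab, "gA", cells=["c1", "c2", "c3"])
        assert list(counts) == [2, 0, 2]
        assert (counts <= 2).all()  # bounded by annotated transcript number

    def test_unknown_gene_rejected(self):
        tx, g2t = _toy_table()
        tab = splicing.relative_abundance(tx, g2t)
        with pytest.raises(KeyError):
            splicing.variants_per_cell(tab, "gZ")


class TestVariantAssociation:
    def _table_from_detection(self, det: np.ndarray) -> pd.DataFrame:
        n_tx, n_cells = det.shape
        rows = []
        for c in range(n_cells):
            col = det[:, c]
            if not col.any():
                continue
            for t in range(n_tx):
                if col[t]:
                    rows.append(
                        ("g", f"t{t}", f"c{c}", 1.0, 1.0 / col.sum())
                    )
        return pd.DataFrame(rows, columns=list(splicing.ABUNDANCE_COLUMNS))

    def test_perfect_coexpression_and_exclusion(self):
        det = np.array(
            [
                [1, 1, 0, 0, 1, 0],
                [1, 1, 0, 0, 1, 0],  # same cells as t0 -> phi 1
                [0, 0, 1, 1, 0, 1],  # complementary -> phi -1
            ],
            dtype=bool,
        )
        tab = self._table_from_detection(det)
        out = splicing.variant_association(tab, "g")
        assert out.loc["t0", "t1"] == pytest.approx(1.0)
        assert out.loc["t0", "t2"] == pytest.approx(-1.0)

    def test_hand_computed_phi(self):
        # 2x2 detection table a=3, b=1, c=1, d=3 -> phi = 8/16 = 0.5
        det = np.array(
            [
                [1, 1, 1, 1, 0, 0, 0, 0],
                [1, 1, 1, 0, 1, 0, 0, 0],
            ],
            dtype=bool,
        )
        # every cell must express the gene for d cells to count: add a third
        # always-on transcript so all 8 cells are in the table
        det = np.vstack([det, np.ones(8, dtype=bool)])
        tab = self._table_from_detection(det)
        out = splicing.variant_association(tab, "g")
        assert out.loc["t0", "t1"] == pytest.approx(0.5)

    def test_few_cells_warn_all_missing(self):
        det = np.array([[1, 1], [0, 1]], dtype=bool)
        tab = self._table_from_detection(det)
        with pytest.warns(UserWarning, match="< 3 cells"):
            out = splicing.variant_association(tab, "g")
        assert out.isna().all().all()


def test_mean_abundance_converges_to_dirichlet_mean():
    """Planted symmetric Dirichlet: recovered per-variant means -> 1/k."""
    cfg = SimConfig(
        n_groups=1, cells_per_group=500, n_lnc=100, n_coding=0,
        stemness_set_size=5, subtype_set_sizes=(2, 2, 2, 2),
        n_multivariant_genes=3, variants_per_gene=10,
        dirichlet_concentration=5.0, variant_floor=0.0,
        dropout_midpoint=-10.0, seed=21,
    )
    tx, g2t, props = generate_variant_profiles(cfg)
    tab = splicing.relative_abundance(tx, g2t)
    for gene in props:
        sub = tab[tab["gene_id"] == gene]
        mean_ra = sub.groupby("transcript_id")["rel_abund"].sum() / sub["cell_id"].nunique()
        assert np.abs(mean_ra - 0.1).max() < 0.05
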