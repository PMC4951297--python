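"""Descriptive heterogeneity: detection rates, correlations, PCA, panels.

Shows that cells correlate more within than between tumors, that PCA on
top-variance genes separates tumors of origin, and builds the
union-of-most-abundant gene panel from the population samples.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import RESULTS, cohort, ensure_dirs, population, processed

from lnchet import preprocess, structure


def main() -> None:
    ensure_dirs()
    _cfg, m, meta, _annot, _truth = cohort()
    logged, genes, cells, z = processed()
    filtered = logged.subset(features=genes, samples=cells)

    pct = structure.percent_expressed(m.subset(samples=cells), genes)
    pct.rename("fraction_detected").rename_axis("sample_id").to_frame().to_csv(
        os.path.join(RESULTS, "03_percent_expressed.tsv"), sep="\t", float_format="%.4g"
    )

    corr = structure.pairwise_correlations(filtered, meta[meta["sample_id"].isin(cells)])
    corr.group_summary.to_csv(
        os.path.join(RESULTS, "03_correlation_summary.tsv"), sep="\t",
        index=False, float_format="%.4g",
    )
    med = corr.pairs.groupby("within_group")["r"].median()

    hv = structure.top_variance_genes(filtered, 500)
    pca = structure.run_pca(filtered, hv)
    pca.coordinates.join(meta.set_index("sample_id")["group"]).to_csv(
        os.path.join(RESULTS, "03_pca_coordinates.tsv"), sep="\t", float_format="%.4g"
    )

    pop, _pop_meta = population()
    pop_logged = preprocess.log_transform(pop.subset(features=genes))
    panel = structure.top_abundant_union(pop_logged, 50)
    clust = structure.hier_cluster(filtered.subset(features=panel))
    with open(os.path.join(RESULTS, "03_abundant_panel.txt"), "w") as fh:
        fh.write("\n".join(panel) + "\n")
    with open(os.path.join(RESULTS, "03_panel_dendrogram.newick"), "w") as fh:
        fh.write(structure.linkage_to_newick(clust.row_linkage, panel) + "\n")

    print(f"median detection rate per cell: {pct.median():.1%}")
    print(f"median pairwise r within tumor {med[True]:.3f} vs between {med[False]:.3f}")
    print(f"PCA variance fractions: {[round(float(v), 3) for v in pca.variance_fractions]}")
    print(f"abundant-union panel: {len(panel)} genes (50 per population sample)")


if __name__ == "__main__":
    main()
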