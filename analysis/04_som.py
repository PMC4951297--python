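"""SOM expression portraits: train, map, cluster the u-matrix, test topology.

Trains the toroidal hexagonal map on the 500 highest-variance z-scored
genes, maps every retained gene, seeds clusters at u-matrix minima, checks
that planted coexpression modules land compactly on the lattice, and runs
over-representation of each cluster against the planted gene sets.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import RESULTS, SCRATCH, SEED, cohort, ensure_dirs, processed

from lnchet import som, structure


def main() -> None:
    ensure_dirs()
    _cfg, _m, _meta, _annot, truth = cohort()
    _logged, _genes, _cells, z = processed()

    train_genes = structure.top_variance_genes(z, 500)
    grid = som.SOMGrid(*som.grid_size(500))
    X = z.values.loc[train_genes].to_numpy()
    som.init_codebooks(grid, X, seed=SEED + 1)
    grid, qe = som.train(grid, X, epochs=200, seed=SEED + 2)
    mapping = som.map_genes(grid, z.values)
    u = som.compute_umatrix(grid)
    clusters = som.assign_genes(som.cluster_units(grid, u), mapping)

    pd.DataFrame(
        {"unit": mapping.bmu, "cluster": clusters.gene_cluster}
    ).rename_axis("gene_id").to_csv(os.path.join(RESULTS, "04_gene_clusters.tsv"), sep="\t")
    pd.DataFrame({"u": u, "cluster": clusters.unit_cluster}).rename_axis("unit").to_csv(
        os.path.join(RESULTS, "04_umatrix.tsv"), sep="\t", float_format="%.4g"
    )

    modules = {
        f"module_{k}": [
            g for g in truth.module_membership.index[truth.module_membership == k]
            if g in mapping.bmu.index
        ]
        for k in sorted(truth.module_membership.dropna().unique())
    }
    obs, null_mean, p = som.topology_preservation_test(
        grid, mapping, modules, n_perm=999, seed=SEED + 3
    )

    gene_sets = dict(modules)
    gene_sets["stemness_signature"] = [
        g for g in truth.signature_genes if g in mapping.bmu.index
    ]
    frames = []
    for cl in sorted(set(clusters.gene_cluster)):
        cl_genes = list(clusters.gene_cluster.index[clusters.gene_cluster == cl])
        enr = som.enrich_cluster(cl_genes, gene_sets, list(z.feature_ids))
        enr.insert(0, "cluster", cl)
        frames.append(enr)
    enrich = pd.concat(frames)
    enrich.to_csv(os.path.join(RESULTS, "04_cluster_enrichment.tsv"), sep="\t",
                  index=False, float_format="%.4g")

    print(f"map: {grid.xdim}x{grid.ydim} torus, quantization error "
          f"{qe[0]:.2f} -> {qe[-1]:.2f} over 200 epochs")
    print(f"u-matrix seeds {len(clusters.seeds)} clusters")
    print(f"planted modules sit {obs:.2f} lattice units apart on average vs "
          f"{null_mean:.2f} for random sets (permutation p = {p:.3g})")
    top = enrich[enrich["q"] < 0.05]
    print(f"{len(top)} (cluster, gene-set) pairs enriched at q < 0.05")


if __name__ == "__main__":
    main()
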