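"""End-to-end orchestration of the analysis stages.

One YAML config drives: (optional) simulation -> preprocessing -> descriptive
structure -> SOM portraits and clustering -> splice-variant analysis ->
stemness/subtype signatures.  Every stage writes plain-text tables into its
own subdirectory of the output directory, and a JSON manifest records
parameters, per-stage status and SHA-256 checksums of every output file so
a rerun with the same config can be verified byte for byte.  All randomness
derives from the single global seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from importlib.metadata import version as pkg_version

import numpy as np
import pandas as pd
import yaml

from . import io, preprocess, signatures, simulate, som, splicing, structure
from .matrix import POPULATION_CONTROL, SINGLE_CELL, ExpressionMatrix

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "structure", "som", "splice", "signatures")

DEFAULTS: dict = {
    "seed": 0,
    "simulate": {"enabled": True, "top_frac": 0.25},
    "inputs": {},
    "preprocess": {"thr_all": 2.0, "thr_group": 4.0, "min_frac": 0.5},
    "structure": {"top_n": 500, "top_k_abundant": 50},
    "som": {
        "train_n": 500,
        "epochs": 200,
        "alpha": [0.05, 0.01],
        "radius_end": 2.0,
        "n_pcs": 10,
        "neighborhood": "bubble",
        "gmt": None,
    },
    "splice": {"min_variants": 10, "dom_threshold": 0.5},
    "signatures": {"alpha": 0.05, "n_random": 100, "q": 0.01},
}


def load_config(path: str) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULTS, user)


def _merge(base: dict, override: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict) -> list[str]:
    """Return a list of problems (empty = valid); checks paths and schema."""
    problems = []
    for key in ("seed",):
        if key not in config:
            problems.append(f"missing key: {key}")
    sim = config.get("simulate", {})
    if not sim.get("enabled", False):
        inputs = config.get("inputs", {})
        for key in ("expression", "metadata"):
            path = inputs.get(key)
            if not path:
                problems.append(f"inputs.{key}: required when simulation is disabled")
            elif not os.path.exists(path):
                problems.append(f"inputs.{key}: file not found: {path}")
    gmt = config.get("som", {}).get("gmt")
    if gmt and not os.path.exists(gmt):
        problems.append(f"som.gmt: file not found: {gmt}")
    q = config.get("signatures", {}).get("q", 0.01)
    if not 0 < q < 0.5:
        problems.append(f"signatures.q: must be in (0, 0.5), got {q}")
    return problems


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_series(s: pd.Series, path: str, name: str, index_name: str) -> None:
    df = s.rename(name).to_frame()
    df.index.name = index_name
    df.to_csv(path, sep="\t", float_format="%.6g")


def run_all(config: dict, outdir: str) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    os.makedirs(outdir, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {
        "package_version": pkg_version("lnchet"),
        "seed": seed,
        "parameters": config,
        "stages": {},
        "outputs": {},
    }

    def finish_stage(stage: str, stage_dir: str) -> None:
        files = sorted(
            os.path.join(stage_dir, f) for f in os.listdir(stage_dir)
            if os.path.isfile(os.path.join(stage_dir, f))
        )
        for f in files:
            manifest["outputs"][os.path.relpath(f, outdir)] = _sha256(f)
        manifest["stages"][stage] = "completed"

    def fail(stage: str, exc: Exception) -> None:
        manifest["stages"][stage] = f"failed: {exc}"
        _write_manifest(manifest, outdir)

    # ---- simulate (or load) -------------------------------------------------
    stage_dir = os.path.join(outdir, "simulate")
    sim_cfg = config["simulate"]
    try:
        if sim_cfg.get("enabled", True):
            os.makedirs(stage_dir, exist_ok=True)
            fields = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in sim_cfg.items()
                if k not in ("enabled", "top_frac")
            }
            cfg = simulate.SimConfig(seed=seed, **fields)
            cohort, meta, annot, truth = simulate.generate_cohort(cfg)
            pop, pop_meta = simulate.generate_population_pairs(
                cohort, meta, truth, sim_cfg.get("top_frac", 0.25)
            )
            tx, g2t, _props = simulate.generate_variant_profiles(
                cfg, gene_tpm=cohort, genes=truth.multivariant_genes
            )
            io.write_expression_tsv(cohort, os.path.join(stage_dir, "expression.tsv"))
            io.write_metadata_tsv(meta, os.path.join(stage_dir, "metadata.tsv"))
            io.write_expression_tsv(pop, os.path.join(stage_dir, "population.tsv"))
            io.write_metadata_tsv(pop_meta, os.path.join(stage_dir, "population_metadata.tsv"))
            io.write_expression_tsv(tx, os.path.join(stage_dir, "transcripts.tsv"))
            io.write_gene_map_tsv(g2t, os.path.join(stage_dir, "gene_map.tsv"))
            truth_json = {
                "stemness_latent": {k: round(float(v), 6) for k, v in truth.stemness_latent.items()},
                "subtype_label": dict(truth.subtype_label),
                "signature_genes": truth.signature_genes,
                "classifier_genes": truth.classifier_genes,
            }
            with open(os.path.join(stage_dir, "truth.json"), "w") as fh:
                json.dump(truth_json, fh, indent=1, sort_keys=True)
            annot_table = annot.table
            finish_stage("simulate", stage_dir)
        else:
            inputs = config["inputs"]
            cohort = io.read_expression_tsv(inputs["expression"])
            meta = io.read_metadata_tsv(inputs["metadata"])
            pop = pop_meta = tx = g2t = truth = annot_table = None
            if inputs.get("population"):
                pop = io.read_expression_tsv(inputs["population"])
                pop_meta = io.read_metadata_tsv(inputs["population_metadata"])
            if inputs.get("transcript_expression"):
                tx = io.read_expression_tsv(inputs["transcript_expression"])
                g2t = io.read_gene_map_tsv(inputs["gene_map"])
            manifest["stages"]["simulate"] = "skipped"
    except Exception as exc:
        fail("simulate", exc)
        raise

    # ---- preprocess ---------------------------------------------------------
    stage_dir = os.path.join(outdir, "preprocess")
    try:
        os.makedirs(stage_dir, exist_ok=True)
        pp = config["preprocess"]
        logged = preprocess.log_transform(cohort)
        genes = preprocess.select_genes(logged, meta, pp["thr_all"], pp["thr_group"])
        cells = preprocess.select_cells(logged, genes, pp["min_frac"])
        filtered = logged.subset(features=genes, samples=cells)
        z = preprocess.zscore(filtered)
        with open(os.path.join(stage_dir, "selected_genes.txt"), "w") as fh:
            fh.write("\n".join(genes) + "\n")
        with open(os.path.join(stage_dir, "retained_cells.txt"), "w") as fh:
            fh.write("\n".join(cells) + "\n")
        io.write_expression_tsv(filtered, os.path.join(stage_dir, "log_expression.tsv"))
        io.write_expression_tsv(z, os.path.join(stage_dir, "zscores.tsv"))
        finish_stage("preprocess", stage_dir)
    except Exception as exc:
        fail("preprocess", exc)
        raise

    # ---- structure ----------------------------------------------------------
    stage_dir = os.path.join(outdir, "structure")
    try:
        os.makedirs(stage_dir, exist_ok=True)
        st = config["structure"]
        meta_cells = meta[meta["sample_id"].isin(cells)]
        pct = structure.percent_expressed(cohort.subset(samples=cells), genes)
        _write_series(pct, os.path.join(stage_dir, "percent_expressed.tsv"),
                      "fraction_detected", "sample_id")
        corr = structure.pairwise_correlations(filtered, meta_cells)
        corr.pairs.to_csv(
            os.path.join(stage_dir, "correlations.tsv"), sep="\t", index=False,
            float_format="%.6g",
        )
        corr.group_summary.to_csv(
            os.path.join(stage_dir, "correlation_summary.tsv"), sep="\t", index=False,
            float_format="%.6g",
        )
        top_n = min(st["top_n"], filtered.shape[0])
        hv_genes = structure.top_variance_genes(filtered, top_n)
        pca = structure.run_pca(filtered, hv_genes)
        pca.coordinates.to_csv(
            os.path.join(stage_dir, "pca_coordinates.tsv"), sep="\t", float_format="%.6g"
        )
        pd.Series(pca.variance_fractions, name="variance_fraction").to_csv(
            os.path.join(stage_dir, "pca_variance.tsv"), sep="\t", float_format="%.6g"
        )
        if pop is not None:
            pop_logged = preprocess.log_transform(pop)
            ctrl_ids = [
                s for s in pop_logged.sample_ids
                if s in set(pop_meta.loc[pop_meta["kind"].isin(
                    [POPULATION_CONTROL, "gsc_culture", "dgc_culture"]), "sample_id"])
            ]
            panel = structure.top_abundant_union(
                pop_logged.subset(features=genes, samples=ctrl_ids),
                min(st["top_k_abundant"], len(genes)),
            )
            with open(os.path.join(stage_dir, "top_abundant_union.txt"), "w") as fh:
                fh.write("\n".join(panel) + "\n")
            clust = structure.hier_cluster(filtered.subset(features=panel))
            with open(os.path.join(stage_dir, "dendrogram.newick"), "w") as fh:
                fh.write(structure.linkage_to_newick(clust.row_linkage, panel) + "\n")
        finish_stage("structure", stage_dir)
    except Exception as exc:
        fail("structure", exc)
        raise

    # ---- som ----------------------------------------------------------------
    stage_dir = os.path.join(outdir, "som")
    try:
        os.makedirs(stage_dir, exist_ok=True)
        sm = config["som"]
        train_n = min(sm["train_n"], z.shape[0])
        train_genes = structure.top_variance_genes(z, train_n)
        xdim, ydim = som.grid_size(train_n)
        grid = som.SOMGrid(xdim, ydim)
        training = z.values.loc[train_genes].to_numpy()
        som.init_codebooks(grid, training, n_pcs=sm["n_pcs"], seed=seed + 1)
        grid, qe = som.train(
            grid, training, epochs=sm["epochs"], alpha=tuple(sm["alpha"]),
            radius=(None, sm["radius_end"]), neighborhood=sm["neighborhood"],
            seed=seed + 2,
        )
        mapping = som.map_genes(grid, z.values)
        umatrix = som.compute_umatrix(grid)
        clusters = som.assign_genes(som.cluster_units(grid, umatrix), mapping)
        pd.DataFrame(grid.codebook).to_csv(
            os.path.join(stage_dir, "codebook.tsv"), sep="\t", float_format="%.6g"
        )
        pd.DataFrame(
            {
                "unit": mapping.bmu,
                "cluster": clusters.gene_cluster,
                "quantization_error": mapping.quantization_error,
            }
        ).rename_axis("gene_id").to_csv(
            os.path.join(stage_dir, "gene_units.tsv"), sep="\t", float_format="%.6g"
        )
        pd.DataFrame(
            {"u": umatrix, "cluster": clusters.unit_cluster}
        ).rename_axis("unit").to_csv(
            os.path.join(stage_dir, "umatrix.tsv"), sep="\t", float_format="%.6g"
        )
        portraits = pd.DataFrame(
            {c: som.cell_component(mapping, z.values, c, grid.n_units) for c in z.sample_ids}
        ).rename_axis("unit")
        portraits.to_csv(
            os.path.join(stage_dir, "portraits.tsv"), sep="\t", float_format="%.6g"
        )
        gene_sets = io.read_gmt(sm["gmt"]) if sm.get("gmt") else None
        if gene_sets is None and truth is not None:
            gene_sets = {
                f"module_{m}": list(truth.module_membership.index[truth.module_membership == m])
                for m in sorted(truth.module_membership.dropna().unique())
            }
            gene_sets["stemness_signature"] = truth.signature_genes
        if gene_sets:
            frames = []
            for cl in sorted(set(clusters.gene_cluster)):
                cl_genes = list(clusters.gene_cluster.index[clusters.gene_cluster == cl])
                enr = som.enrich_cluster(cl_genes, gene_sets, list(z.feature_ids))
                enr.insert(0, "cluster", cl)
                frames.append(enr)
            pd.concat(frames).to_csv(
                os.path.join(stage_dir, "enrichment.tsv"), sep="\t", index=False,
                float_format="%.6g",
            )
        pd.Series(qe, name="mean_quantization_error").rename_axis("epoch").to_csv(
            os.path.join(stage_dir, "training_error.tsv"), sep="\t", float_format="%.6g"
        )
        finish_stage("som", stage_dir)
    except Exception as exc:
        fail("som", exc)
        raise

    # ---- splice -------------------------------------------------------------
    stage_dir = os.path.join(outdir, "splice")
    try:
        if tx is not None:
            os.makedirs(stage_dir, exist_ok=True)
            sp = config["splice"]
            mv = splicing.select_multivariant_genes(g2t, sp["min_variants"])
            tab = splicing.relative_abundance(
                tx, g2t[g2t["gene_id"].isin(mv)], cells=[c for c in tx.sample_ids if c in set(cells)] or None
            )
            tab.to_csv(
                os.path.join(stage_dir, "abundance.tsv"), sep="\t", index=False,
                float_format="%.6g",
            )
            dom = splicing.dominant_variants(tab, sp["dom_threshold"])
            dom.per_gene.to_csv(
                os.path.join(stage_dir, "dominance_per_gene.tsv"), sep="\t", index=False
            )
            dom.per_cell.to_csv(
                os.path.join(stage_dir, "dominance_per_cell.tsv"), sep="\t", index=False
            )
            _write_series(
                splicing.variant_frequency(tab),
                os.path.join(stage_dir, "frequency.tsv"), "n_cells", "transcript_id",
            )
            if len(tab):
                exemplar = tab["gene_id"].iloc[0]
                _write_series(
                    splicing.variants_per_cell(tab, exemplar),
                    os.path.join(stage_dir, "variants_per_cell.tsv"), "n_variants", "cell_id",
                )
                assoc = splicing.variant_association(tab, exemplar)
                assoc.to_csv(
                    os.path.join(stage_dir, "association.tsv"), sep="\t",
                    float_format="%.6g",
                )
            finish_stage("splice", stage_dir)
        else:
            manifest["stages"]["splice"] = "skipped"
    except Exception as exc:
        fail("splice", exc)
        raise

    # ---- signatures ---------------------------------------------------------
    stage_dir = os.path.join(outdir, "signatures")
    try:
        os.makedirs(stage_dir, exist_ok=True)
        sg = config["signatures"]
        # biotype-specific universes where annotation is available: the
        # stemness/subtype analyses score against the lncRNA library mean
        if annot_table is not None:
            lnc_all = set(annot_table.loc[annot_table["biotype"] == "lncRNA", "gene_id"])
            z_lnc = z.subset(features=[g for g in z.feature_ids if g in lnc_all])
            z_coding = z.subset(features=[g for g in z.feature_ids if g not in lnc_all])
            sig_pool = [g for g in genes if g in lnc_all]
        else:
            z_lnc = z_coding = z
            sig_pool = genes
        if pop is not None:
            pop_logged = preprocess.log_transform(pop.subset(features=sig_pool))
            sig = signatures.derive_stemness_signature(pop_logged, pop_meta, sg["alpha"])
            sig.stats.rename_axis("gene_id").to_csv(
                os.path.join(stage_dir, "stemness_signature.tsv"), sep="\t",
                float_format="%.6g",
            )
            present = [g for g in sig.genes if g in set(z_lnc.feature_ids)]
            if len(present) >= 2:
                sig_use = signatures.SignatureSet("stemness", present)
                scores = signatures.signature_score(z_lnc, sig_use)
                _write_series(
                    scores, os.path.join(stage_dir, "stemness_scores.tsv"),
                    "stemness_score", "sample_id",
                )
                grouping = meta.set_index("sample_id")["group"]
                grad = signatures.gradient_significance(
                    z_lnc, sig_use, grouping, sg["n_random"], seed=seed + 3
                )
                grad.to_csv(
                    os.path.join(stage_dir, "gradient_significance.tsv"), sep="\t",
                    index=False, float_format="%.6g",
                )
        if truth is not None:
            consistency = {}
            calls_by_biotype = {}
            for bt, sets in truth.classifier_genes.items():
                zb = z_lnc if bt == "lncRNA" else z_coding
                zset = set(zb.feature_ids)
                classifiers = {
                    s: signatures.SignatureSet(s, [g for g in gl if g in zset])
                    for s, gl in sets.items()
                    if any(g in zset for g in gl)
                }
                if len(classifiers) < len(sets):
                    logger.warning("%s: some classifier sets lost to filtering", bt)
                    continue
                scores = signatures.subtype_scores(zb, classifiers)
                cutoffs = signatures.subtype_cutoffs(
                    zb, classifiers, sg["n_random"], sg["q"], seed=seed + 4
                )
                call = signatures.classify_cells(scores, cutoffs)
                calls_by_biotype[bt] = call
                scores.rename_axis("sample_id").to_csv(
                    os.path.join(stage_dir, f"subtype_scores_{bt}.tsv"), sep="\t",
                    float_format="%.6g",
                )
                with open(os.path.join(stage_dir, f"subtype_cutoffs_{bt}.json"), "w") as fh:
                    json.dump({k: round(v, 6) for k, v in cutoffs.items()}, fh,
                              indent=1, sort_keys=True)
                out = call.passing.copy()
                out["n_subtypes"] = call.n_subtypes
                out["top_label"] = call.top_label()
                out.rename_axis("sample_id").to_csv(
                    os.path.join(stage_dir, f"subtype_calls_{bt}.tsv"), sep="\t"
                )
            if len(calls_by_biotype) == 2:
                a, b = calls_by_biotype.values()
                consistency["lnc_vs_coding_percent"] = round(
                    signatures.classification_consistency(a, b), 4
                )
                with open(os.path.join(stage_dir, "consistency.json"), "w") as fh:
                    json.dump(consistency, fh, indent=1, sort_keys=True)
        finish_stage("signatures", stage_dir)
    except Exception as exc:
        fail("signatures", exc)
        raise

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: str) -> None:
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
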