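# lnchet — single-cell lncRNA expression heterogeneity

Tumors are not transcriptionally uniform: individual cells from one tumor
differ in which long noncoding RNAs (lncRNAs) they express, how strongly,
which splice variants they use, how stem-like they are, and which molecular
subtype they resemble. `lnchet` implements an end-to-end analysis of that
heterogeneity for glioblastoma-style single-cell RNA-seq cohorts quantified
in TPM, aimed at computational biologists who want each step as a tested,
reusable library function:

- **Preprocessing** — log2(TPM+1); keep genes with mean > 2 overall or > 4
  in one tumor; keep cells detecting ≥ half of those genes; per-gene
  z-scores.
- **Descriptive structure** — per-cell detection rates, within- vs
  between-tumor Pearson correlations, PCA on top-variance genes,
  union-of-most-abundant gene panels, hierarchical clustering with Newick
  export.
- **SOM expression portraits** — a toroidal hexagonal self-organizing map
  (5·√N units, PCA initialization, online training with a linearly
  declining learning rate 0.05 → 0.01 and radius d → 2) trained on gene
  z-score vectors; u-matrix clustering seeded at local minima; per-cell
  component portraits; hypergeometric gene-set enrichment of clusters.
- **Splicing** — within-gene relative variant abundances per cell, dominant
  variants (relative abundance > 0.5), detection frequencies, variants per
  cell, and phi-coefficient co-expression/mutual-exclusivity of variants.
- **Signatures** — a stemness signature from paired t-tests on stem-like
  (GSC) vs differentiated (DGC) population cultures; per-cell score
  s(c) = mean_{g∈sig} z(g,c) − mean_{g∈universe} z(g,c); within-tumor
  gradient SD tested against 100 size-matched random gene sets; subtype
  scores for proneural/neural/mesenchymal/classical classifier sets with
  empirical 1% cutoffs, hybrid states allowed.
- **Synthetic cohorts** — a generator that plants tumor structure, logistic
  dropout, coexpression modules, a stemness gradient, subtype labels and
  Dirichlet splice-variant profiles, so the whole pipeline is testable
  without any download.

See `docs/methods.md` for the model details and design decisions.

## Worked example

The numbered drivers under `analysis/` run the full study on a seeded
synthetic cohort (5 tumors × 40 cells, 2,000 lncRNAs + 5,000 coding genes)
and write tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_structure.py
python analysis/04_som.py
python analysis/05_splicing.py
python analysis/06_signatures.py
```

Output from an actual run (seed 7):

```
3610/7000 genes pass the two-tier abundance filter (1012 lncRNAs); 200/200 cells detect >= half of them
median pairwise r within tumor 0.569 vs between 0.431
map: 11x10 torus, quantization error 13.60 -> 12.89 over 200 epochs
u-matrix seeds 8 clusters
planted modules sit 3.57 lattice units apart on average vs 3.78 for random sets (permutation p = 0.001)
31 genes with >= 10 annotated variants; 367 splice events detected
a dominant variant (>50% of the gene's TPM) exists in 25.1% of (gene, cell) pairs
stemness signature: 77 genes, recall of planted set 100%
per-cell stemness score vs planted latent: Spearman rho = 0.941
gradient SD exceeds all random sets in every tumor (max empirical p = 0.0099)
subtype primary-label accuracy 92.0%; 3.0% of cells in hybrid states
lncRNA vs coding classification consistency: 89.0%
```

Reading this: cells correlate more with cells of their own tumor than with
other tumors (0.57 vs 0.43), the SOM places genes of the same planted
coexpression module significantly closer on the lattice than chance
(p = 0.001), most (gene, cell) pairs express a mixture of splice variants
with a single dominant variant in a quarter of them, the paired GSC/DGC test
recovers every planted stemness gene, and the per-cell stemness score
reconstructs the planted differentiation gradient almost perfectly
(ρ = 0.94).

The same pipeline runs from one YAML config:

```bash
lnchet pipeline run --config configs/demo.yaml --outdir out/
lnchet pipeline validate --config configs/demo.yaml
```

and each stage has its own subcommand (`lnchet simulate|preprocess|
structure|som|splice|signatures`) for externally produced TSV/MTX/GMT
inputs. Two runs with the same config produce byte-identical outputs; the
`manifest.json` records parameters and SHA-256 checksums of every file.

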