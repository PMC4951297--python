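# Methods

`lnchet` re-implements, as a tested library plus analysis drivers, a
single-cell workflow for characterizing cell-to-cell heterogeneity of lncRNA
expression in tumors: abundance filtering and normalization of TPM matrices,
self-organizing-map (SOM) expression portraits with u-matrix clustering,
splice-variant usage statistics, a stemness signature scored against
random-set nulls, and molecular-subtype calling with empirical cutoffs.
Because the workflow's published inputs are an external repository accession,
the package ships a synthetic cohort generator that plants every piece of
structure the downstream analyses estimate; all tests and the acceptance
script run on it.

## Preprocessing

Input is a nonnegative genes x samples TPM matrix. Values are transformed to
log2(TPM+1) (so 0 stays 0). Genes are kept when their mean log2(TPM+1)
strictly exceeds 2 across all single cells, or strictly exceeds 4 within at
least one tumor — both inequalities strict, as printed. Cells are kept when
they detect (TPM > 0) at least half of the retained genes, inclusive.
Retained rows are z-scored per gene; we use the sample standard deviation
(n−1), a convention the source procedure leaves unstated, and record it in
output metadata. Genes with zero variance are dropped before z-scoring:
their z-score is undefined and a constant gene carries no cell-to-cell
information. Whether population samples enter the filter averages is
configurable (`kinds` argument); the default uses single cells only.

## SOM portraits

Genes are the training items; each gene's vector is its z-score profile
across retained cells. The lattice is hexagonal (axial coordinates with
odd-row offset) and toroidal. Its size follows the M = 5·√N heuristic
(N training genes), with xdim = round(√M), ydim = round(M/xdim). Lattice
distances are computed as the minimum planar distance over the nine torus
images — exact and simple. Neighbor sets use offset arithmetic with modular
wrap, which always yields six neighbors; when the row count is odd the wrap
seam is combinatorially consistent but not perfectly symmetric geometrically
(a property of any offset hex torus with odd rows). Sizing typically
produces near-square, even-dimension grids where the issue does not arise.

Codebooks are initialized in the span of the top 10 principal components:
the column axis spans ±2 SD of PC1, the row axis ±2 SD of PC2, and
remaining PC coordinates are small seeded perturbations. Training is online
(sequential): each presented gene finds its best-matching unit (BMU;
Euclidean distance, ties to the lowest unit index) and all units within the
current radius move toward it by the current learning rate (bubble
neighborhood; a Gaussian kernel is available). The learning rate declines
linearly 0.05 → 0.01 and the radius from d → 2 over all updates
(epochs × genes; 200 epochs by default), where d is the 2/3 quantile of all
pairwise unit distances. The schedule interpolates per presentation; a
per-epoch option exists because the convention differs between SOM
implementations. The per-epoch mean quantization error is accumulated at
presentation time, so monitoring training costs nothing extra.

After training, *all* analysis genes (not only the training subset) are
mapped to BMUs. The u-matrix assigns each unit the mean Euclidean codebook
distance to its six neighbors (the unit-averaged variant). Clusters are
seeded at u-matrix local minima — strictly below all six neighbors, with a
connected equal-valued plateau that jointly beats its border contributing a
single seed (its lowest unit index). Every other unit joins the seed with
the nearest codebook, ties to the lowest seed index. The cluster count is
therefore emergent, not fixed. A cell's "component portrait" gives each unit
the mean z-score, in that cell, of the genes it houses. Cluster gene lists
are tested for over-representation in user-supplied GMT gene sets with a
one-sided hypergeometric tail and Benjamini–Hochberg correction across sets
(a local replacement for web-server enrichment, which is out of scope).

## Splice-variant usage

From a transcript-level TPM matrix and a gene → transcript map, the
relative abundance of transcript t in cell c is tpm(t,c) divided by the
gene's total in that cell, defined only where the total is positive;
zero-TPM variants are excluded ("variants without expression"). Genes with
at least 10 annotated variants (annotation counts, not detected counts — a
config flag switches) are the multi-variant set. A variant *dominates* a
(gene, cell) when its relative abundance strictly exceeds 0.5 — the smallest
threshold that guarantees uniqueness by pigeonhole. Pairwise variant
association uses the phi coefficient of detection indicators across
expressing cells (+1 co-expression, −1 mutual exclusivity), since the
relevant observations concern presence patterns; abundance Pearson is
available by option.

## Stemness signature and subtype calls

The signature derives from paired stem-like (GSC) and differentiated (DGC)
population cultures: one paired t-test per gene over the per-pair
(GSC − DGC) differences, keeping genes with p < 0.05 and positive mean
difference. A per-pair reading of the pairing ("positive in every pair") is
available behind a flag; the single-test reading is the default because a
per-pair t-test on one observation is undefined. Difference vectors with
zero variance but positive mean are perfectly consistent effects and are
kept with p recorded as 0 (flagged). No multiple-testing correction is
applied at this step, matching the raw-threshold procedure; BH q-values are
reported alongside for transparency.

A cell's signature score is the mean z-score of the signature genes minus
the mean z-score of the scoring universe (the lncRNA library when biotypes
are annotated), making the score invariant to per-cell shifts. The
within-tumor *stemness gradient* is the SD of per-cell scores in one tumor;
its significance comes from 100 size-matched random gene sets drawn without
replacement from the same universe, with the empirical estimator
p = (1 + #{null SD ≥ observed}) / (1 + 100), which cannot return zero.

Subtype scores apply the same scoring to four classifier sets (proneural,
neural, mesenchymal, classical). Cutoffs are empirical: 100 size-matched
random sets are scored in every cell and the per-subtype cutoff is the 99th
percentile of the pooled null scores (pooling across cells; a per-cell
variant is available). A cell passes every subtype whose score strictly
exceeds its cutoff — possibly several (hybrid states) or none
(unclassified). Consistency between two classifications (e.g. lncRNA-based
vs coding-based) is the percentage of cells whose top-scoring passing
subtype agrees, counting two unclassified calls as agreement; the original
~77% figure has no published definition, so this explicit metric is our
choice.

## Synthetic cohort generator

The generator emulates the *structure* of a multi-tumor single-cell TPM
study; the source data's dropout and abundance distributions are not
characterized anywhere, so the defaults are realistic free parameters, not
estimates. Per gene g and cell c on the log2 scale:

    mu(g,c) = baseline(g) + groupshift(g, tumor(c))
              + module_shift · activity(module(g), c)
              + stemness_effect · latent(c)        [signature genes]
              + subtype effects                    [classifier genes]

with TPM = max(2^(mu + noise) − 1, 0), then zeroed with probability
1 − sigmoid(steepness · (mu − midpoint)) — logistic dropout on the
underlying mean, chosen over negative-binomial counts because the whole
pipeline operates in TPM space. Defaults: 5 tumors × 40 cells; 2,000
lncRNAs + 5,000 coding genes; baseline ~ N(2.5, 1.5²) log2 units; noise SD
0.5 (chosen so that the planted stemness gradient at effect 2 remains
recoverable at Spearman ρ > 0.8, per the generator's calibration contract);
dropout midpoint 1.0, steepness 1.0 (≈27% zeros at these baselines);
tumor shift SD 0.5; 4 coexpression modules of 50 genes at shift 1; a
31-gene stemness signature at effect 2; four 8-gene classifier sets per
biotype at effect 2, with 20% of cells carrying a half-strength secondary
subtype (hybrid states); 31 multi-variant genes with 12 variants each and
Dirichlet concentration 0.3 (small concentration ⇒ single-variant
dominance), flooring proportions below 0.01 to exactly zero and
renormalizing so transcript TPMs sum exactly to the gene TPM.

Three deliberate design points. Modules act through a per-cell latent
activity ~ N(0,1) scaled by `module_shift`: a constant per-gene offset would
vanish under per-gene z-scoring, leaving nothing for the SOM to organize.
Planted signature/classifier baselines are drawn from the upper half of the
baseline distribution, because published signature and classifier sets are
by construction members of the retained abundant library; fully random
baselines would plant genes the abundance filter is designed to remove.
The stemness latent is Uniform[0,1] per cell, and the paired GSC/DGC
population samples are per-gene means over the top and bottom quarter of
cells by that latent — so "GSC up" is true by construction for signature
genes and the paired test has a planted answer. All randomness flows from
one seed through named substreams (baseline, noise, dropout, Dirichlet,
latent), so components are independently reproducible and a fixed seed
gives bit-identical output.

What the generator does *not* emulate: read-level sampling, batch effects,
doublets, gene length/GC biases, empirical dropout-vs-mean curves of any
particular protocol, or correlated structure beyond the planted modules.
Passing tests therefore demonstrate that the implementation recovers known
planted structure under a plausible noise model — not that the original
biological findings replicate on real data.

## Numerical choices and problem sizes

BMU and seed-assignment ties break to the lowest unit index; sorts are
stable so variance ranking preserves input order among ties. Empirical
p-values use (1+k)/(1+n). The dominance threshold comparison, both filter
thresholds, and the subtype cutoff are strict. The test suite's recovery
sweeps use 20 independent cohorts of 2,000 genes × 200 cells (SOM topology,
stemness, subtypes), 999-permutation lattice-compactness tests, and
100-run null calibrations on effect-free cohorts; the bundled demo pipeline
uses a 600-gene, 100-cell cohort. These sizes make every sweep reproducible
on a single CPU in minutes while leaving the statistical margins wide
(observed: recall ≥ 0.93, ρ ≈ 0.9–0.94, subtype accuracy ≥ 0.94 across
seeds).

## Known limitations

The u-matrix clustering returns an emergent cluster count that can be
sensitive to training noise on small maps. The offset-hex torus with an odd
row count has a geometrically imperfect seam (documented above). The
hypergeometric enrichment treats gene sets as unordered (no ranked GSEA).
The consistency metric and the dominance threshold are explicit choices
where the source procedure is silent; both are parameters.
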