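# Methods

`thermomem` implements the inference chain used to study transcription-factor
control of heat-stress memory (thermomemory) in plant seedlings: a qPCR
screen of a TF panel across a priming/memory time course, moderated
differential expression over a genotype x condition x timepoint RNA-seq
factorial, promoter-proximal binding-peak annotation, direct-target calling
by genotype discordance, weighted co-expression modules with TF-target
enrichment, and phenotype quantification. A synthetic-data generator with
recorded planted truth makes every stage verifiable without external data.

## Comparative-Ct quantification (`thermomem.qpcr`)

Expression of gene *g* in a sample is scored as `40 − ΔCt`, with
`ΔCt = Ct_g − Ct_ref` against a stable reference gene measured in the same
sample. Both quantities are on a log2 scale (one PCR cycle ≈ one doubling),
so the log2 fold change between two treatment arms at a shared timepoint is
the difference of the two scores (the ΔΔCt identity). Assumptions: equal
amplification efficiency across genes (efficiency estimation is out of
scope) and a reference gene unaffected by treatment.

Operational choices the protocol leaves open, fixed here:

- detection ceiling Ct = 38; a gene is *undetectable in an arm* when no
  sample of that arm yields Ct below the ceiling. Undetectable genes carry
  no ratios and are excluded from clustering and DE calling.
- technical replicates are arithmetic-mean aggregated before ΔCt.
- differential expression: |log2 ratio| ≥ log2(1.5) at **any** timepoint,
  boundary inclusive; direction taken at the timepoint of maximal |ratio|.
- trajectory clustering: Euclidean k-means on the per-gene log2-ratio
  vectors, k-means++ seeding, best of 25 restarts, fixed RNG; labels
  renumbered in decreasing cluster-size order so runs are comparable.
  Isolated missing timepoints are column-mean imputed for clustering only.

## Moderated differential expression (`thermomem.diffexpr`)

Counts are transformed to `log2((count + 0.5)/(libsize + 1) · 1e6)`.
A mean-variance trend (lowess, span 0.5, 2 robustness iterations, on sqrt
residual standard deviations from an unweighted pre-fit against the design)
gives per-observation precision weights (predicted sd⁻⁴); quantile
normalisation onto the column-mean reference distribution is applied after
the trend is fitted and the weights are frozen. All samples are fitted in a
single joint cell-means model over the 18 genotype x condition x timepoint
cells, pooling residual degrees of freedom (36 at 3 replicates).

Empirical-Bayes moderation follows the scaled-F moment-matching route:
with per-gene residual variances `s_g²` on `d_g` df, the prior `(d0, s0²)`
is estimated from the mean and excess variance of `log s_g²` by trigamma
inversion, the posterior variance is
`s̃_g² = (d0·s0² + d_g·s_g²)/(d0 + d_g)`, and the moderated t for a contrast
`c` is `c'β̂ / (s̃_g √(c'(X'WX)⁻¹c))` on `d0 + d_g` df. `d0 = ∞` is used as a
sentinel when the variances show no excess spread. The implementation is
verified against the Bioconductor reference (limma) on shared matrices in
the test suite (agreement to 1e-6 on t).

The genotype-dependent heat response is isolated by the second-order
interaction contrast `(heat − control)_genotype − (heat − control)_WT` per
timepoint. Decisions use Benjamini-Hochberg applied **globally** to the
pooled p-vector across all genes and contrasts, at FDR 0.05 with no logFC
cutoff by default (both configurable).

Diagnostics: Pearson sample-correlation matrix with average-linkage ordering
on `1 − r`, and classical (Torgerson) multidimensional scaling of Euclidean
sample distances (double-centred squared distances, top eigenpairs; negative
eigenvalue mass triggers a non-Euclidean warning).

## Promoter-proximal binding (`thermomem.annotation`)

GFF3 gene models (1-based) and narrowPeak intervals (0-based half-open) are
normalised internally to 1-based inclusive coordinates. The TSS is the
5'-most coordinate of the gene body. Nearest-TSS distance is 0 when the TSS
lies inside the peak, otherwise the gap to the closest peak edge;
equidistant genes are tie-flagged with a deterministic lexicographic winner.
A gene is promoter-bound when ≥1 peak overlaps the open strand-aware window
`(TSS − 1000, TSS)` (reflected for minus-strand genes) or covers the TSS
itself; a summit-based mode is provided since protocols differ on whether
the whole peak or its summit must fall upstream.

## Direct-target calling (`thermomem.targets`)

A gene is a candidate direct target at a timepoint when the OE-vs-WT
interaction decision and the KO-vs-WT decision are significant **in opposite
directions** (conjunction, not disjunction — the biological argument needs
dosage dependence in both directions) *and* the gene is promoter-bound.
Candidates supported at ≥2 of the 3 timepoints pass the commonality filter.
Priming-associated sustained sets come in a strict mode (significant in the
same direction at every timepoint) and a lenient mode (significant at the
first timepoint, same-sign logFC later); strict is the default.

## Co-expression network (`thermomem.coexpr`)

Unsigned weighted network: `a_ij = |cor(g_i, g_j)|^β` with soft power β = 6
by default (the power scan reports the scale-free fit index and mean
connectivity over a grid; the fit index regresses log10 frequency on log10
mean connectivity over 10 equal-width connectivity bins, sign-penalising a
positive slope). Topological overlap
`TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)` feeds
average-linkage clustering of `1 − TOM` with a static cut at height 0.99;
clusters smaller than 30 genes are left unassigned (label 0). The dynamic
tree-cut variant is not implemented; the static cut is a documented
approximation. Module eigengenes are first principal components of the
standardised module expression, sign-anchored to positive mean loading.

TF-target overrepresentation per module is the upper-tail hypergeometric
probability with the network genes as the universe (overrepresentation is
asked relative to clustered genes, not the genome), BH-adjusted jointly
across all module x target-set tests; the intersection target set (genes
bound by all TFs) is tested alongside the per-TF sets.

## Phenotype (`thermomem.phenotype`)

Chlorophyll from DMSO-extract absorbance, protocol coefficients verbatim:
`Chl_a = 0.0127·OD663 − 0.00269·OD645`, `Chl_b = 0.229·OD645 − 0.00488·OD663`,
`Total(g/L) = 0.202·Chl_a + 0.00802·Chl_b`,
`Total(mg/g FM) = (20.2·Chl_a + 8.02·Chl_b)/FM`, ODs scaled by the dilution
factor first. Note the printed coefficient set is internally inconsistent
with the classical Arnon coefficients (0.229 vs 0.0229 for Chl_b; the total
mixes 0.202/0.00802 with 20.2/8.02); it is applied as printed, negative
results are flagged but retained, and a `classic_arnon` switch provides the
standard set, clearly labelled as non-protocol. Fresh-mass ratios are
stressed-mean over control-mean per genotype with a descriptive Welch t;
recovery classes are an input labelling whose proportions are tallied.

## Synthetic data (`thermomem.simulate`)

The generator emulates the study design: 3 genotypes (WT, TF
overexpressor, TF knockout) x 2 conditions x 3 post-priming timepoints x 3
biological replicates, 2000 genes, 50 planted direct targets. Counts are
negative binomial with `var = μ + φμ²`; log2 mean structure = baseline
(U(1,9) relative log-abundance, normalised once so planted effects pass
into count means exactly) + per-timepoint heat effects N(0, 1 log2 unit)
shared across genotypes + the planted heat x genotype interaction (±2 log2
units, opposite sign in OE and KO, each target affecting ≥2 of the 3
timepoints) + a per-module latent sample factor. Library sizes are
log-normal around 5e6.

Noise defaults and why:

- `nb_dispersion = 0.02` (biological CV ≈ 0.14). Each replicate is a pooled
  plate of seedlings of a single accession grown in a controlled chamber;
  for such designs genewise dispersion is typically 0.01–0.04, far below
  the ~0.16 ("BCV 0.4") rule of thumb for heterogeneous human samples.
- `module_latent_sd = 0.6` log2 units, giving within-module correlations
  around 0.7–0.8 — strong co-expression without letting the shared factor
  drown per-gene signal, which would be atypical of real modules.
- qPCR: Ct noise sd 0.15 cycles, reference gene at Ct 20, detection ceiling
  38, a 104-gene panel with 5 trajectory archetypes and 29 planted
  undetectable genes.
- gene models: one synthetic chromosome, non-overlapping genes on both
  strands, intergenic gaps wide enough that decoy peaks can always be
  placed > window+1 bp from every TSS (so decoys never qualify); every
  planted target receives ≥1 peak wholly inside its strand-aware promoter
  window.

What the generator does **not** emulate — so what passing tests do not
show about real data: GC/length biases and mapping artefacts, batch and
lane effects, correlated library-preparation noise, isoform-level
complexity, unbalanced or missing cells, genuine promoter architecture
(bidirectional promoters, nested genes), and binding peaks whose strength
correlates with regulation. Planted-truth recovery demonstrates the
statistical machinery is correct, not that the biological error rates of
the original experiment are reproduced.

## Verification quantities and problem sizes

`scripts/acceptance.py` recomputes, at the sizes given: exact-enumeration
agreement of the hypergeometric tail (all N ≤ 12), brute-force agreement of
nearest-TSS/promoter geometry (50 random instances), empirical-Bayes prior
recovery (5000 genes, d0 = 4, s0² = 2), global-null mean false-discovery
proportion (20 replicates of 2000 genes x 6 contrasts), end-to-end planted
target recovery (default generator, and its zero-effect null), module
recovery and planted enrichment (150 genes, two 60-gene modules), and the
exact worked examples (MDS, BH step-up, chlorophyll). These sizes keep a
full run to well under a minute on one CPU while leaving each check
statistically meaningful.

A note on the global-null check: for BH under a global null the expected
per-run false-discovery proportion equals the nominal level exactly (the
Simes identity), so a finite-seed mean fluctuates around 0.05 rather than
sitting below it; the suite documents the measured value and the test
records this property at its nominal bound.

## Known limitations

- The voom-style weights are estimated from the same data they weight; at
  very small gene counts (< ~10 genes) the trend is skipped and weights
  fall back to 1.
- The static tree cut can split one planted module into sub-branches when
  within-module correlation is weak; the dynamic-cut refinement is out of
  scope.
- Contrast machinery assumes a common design across genes; genes with zero
  residual df are flagged, not tested.
- narrowPeak `summit = -1` falls back to the interval midpoint.
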