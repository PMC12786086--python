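# Methods

## The analysis model

The pipeline treats one scRNA-seq project — several retinal organoids, each a
single sample, spanning control, disease non-treated (NT), and disease
organoids treated with an RK- or CAG-driven *KCNV2* transgene vector — as one
`PotencyAnalysis`. The vector transcript is an ordinary feature row in the
count matrix (as produced by aligning against a reference augmented with the
codon-optimised sequence), distinguished only by its name.

### QC and normalisation

Cells are excluded when total UMIs < 500, mitochondrial fraction > 20% or
ribosomal fraction > 20%; the inequalities are strict, so a 500-UMI cell and
a cell at exactly 20% are kept. Mitochondrial genes are recognised by the
`MT-` name prefix and ribosomal genes by `RPS`/`RPL` prefixes — a naming
convention, configurable by editing the matrix's feature names, adopted
because no curated list is universal. Transgene counts count toward the UMI
total (they are real molecules). Expression is normalised to counts per
million per cell and all per-cell statistics run on log2(CPM + 1); group
means for fold changes and restoration are arithmetic means of CPM (a
`log_scale_means` switch exists for sensitivity analysis).

### Annotation

PCA is computed on the 100 highest-variance log2(CPM + 1) features (variance
ties broken lexicographically; the transgene is never a feature, since it
encodes treatment rather than identity), keeping 7 components with a
deterministic sign convention (largest-magnitude loading positive). Cells are
clustered by Leiden modularity optimisation on the symmetrised Euclidean
30-nearest-neighbour graph, seeded for reproducibility. Cell types come from
an scType-style score: per-gene z-scores across cells, positive markers
weighted 1/(number of types claiming the gene), negative markers subtracted
unweighted, the type sum scaled by √(markers present). Clusters take the
arg-max of summed member scores, falling back to "Unknown" when the best sum
is below (cluster size)/4; a cluster→type override table supports manual
re-annotation. UMAP coordinates are deliberately outside the correctness
surface — they are visualisation only.

### Potency read-outs

*Transduction*: a cell is transgene-positive at ≥ 1 × 10⁻⁴ CPM, which for
UMI data is any nonzero count; percent-positive and mean log2(CPM + 1) in
positive cells are tabulated per sample × cell type, and rod-vs-cone level
comparisons use Kruskal–Wallis with Dunn's post hoc z-tests and
Benjamini–Hochberg correction.

*Disease-model DEGs*: per photoreceptor type, Wilcoxon rank-sum on
log2(CPM + 1) per gene (exact enumeration at pooled n ≤ 10; otherwise the
normal approximation with tie-corrected variance and continuity correction),
BH across tested genes, and a signed fold change on mean CPM
(a'/b' or −b'/a' with a 0.01-CPM offset guarding empty genes, so |FC| ≥ 1
always). A gene is a DEG at BH-adjusted p < α (default 0.05) and |FC| ≥ 1.2,
boundary inclusive. When both a knockout and a patient contrast are present
the disease-model set is their intersection with concordant direction; with a
single disease model the concordance filter cannot apply and the run says so
in its notices.

*Restoration*: improvement = (m_treated − m_disease)/(m_control − m_disease)
on group-mean CPM. Improvement ≥ 0.2 (inclusive) marks a gene restored —
under both vectors by default (`mode="both"`), or either (`mode="any"`),
since published usage varies between the two readings. Overshoot
(improvement > 1) still counts as restored but is flagged. Genes whose
control and disease means coincide in the scoring data are flagged
degenerate and score 0 rather than being dropped. Treated group means use
all cells of the type by default (the bulk-comparison reading); the
`positives_only` mode restricts treated means to transgene-positive cells,
which removes the dilution of the measured improvement by the percent of
cells actually transduced — with 21% RK transduction, an all-cell
improvement is roughly a fifth of the per-transduced-cell effect, so
positives-only is the mode to use when the question is per-cell vector
potency. "Full rescue" flags come from a treated-vs-control Wilcoxon within
the disease-model DEG set (BH over that set only): adjusted p ≥ α.

*Enrichment*: upper-tail hypergeometric over-representation (log-space
evaluation) of a query set against GMT collections, background = genes
detected in at least one QC-passing cell of the relevant cell type
(configurable), set sizes restricted to [3, 2000] after background
intersection, BH across tested terms.

## The synthetic-data generator

`simulate_experiment` emulates the design the pipeline targets: one control
plus NT/RK/CAG disease organoids per genotype arm (knockout by default,
optionally a patient arm as a second project), 2 000 cells per sample and
2 000 endogenous genes by default — matching the scale of real organoid
experiments of this kind, where post-QC samples run roughly 1 000–3 000
cells.

* **Cell types** — eight retinal classes drawn at fixed proportions (rods
  0.31, cones 0.19, Müller glia 0.13, bipolar 0.10, amacrine 0.08,
  horizontal 0.07, progenitors 0.07, other 0.05), the composition of a
  mature day-280 organoid.
* **Counts** — gamma-Poisson (negative binomial) with shared dispersion 2.0
  around per-type expression profiles; library sizes log-normal around
  20 000 UMIs; per-cell mitochondrial/ribosomal fractions are Beta draws
  routed to reserved `MT-`/`RPS`/`RPL` genes so QC operates on names alone.
  5% of cells are forced to fail QC (half by low library, half by high
  mitochondrial content).
* **Markers** — 8 genes per type from a high-expression stratum, expressed
  marker_fold = 8× in their native type and at 2% of baseline elsewhere.
  Canonical retinal markers are highly abundant and near-exclusive; this is
  what makes them dominate the top-variance feature list, and without it a
  variance-ranked feature selection sees mostly sampling noise.
* **Disease effects** — 200 genes per photoreceptor type (disjoint from
  markers and each other) scaled by a signed fold drawn uniformly from
  [1.5, 2.5] with random direction; the same planted set applies to every
  disease genotype, making two-model concordance exact in truth. The ≥1.2
  magnitude floor is enforced at config validation.
* **Transduction** — per (treatment, type) Bernoulli: RK rods/cones 0.21,
  Müller 0.10, others 0.02; CAG 0.50 everywhere. With the default
  composition the RK expectation over all cells is 12.5%. Transgene counts
  are NB with mean 12 in transduced cells only (zero elsewhere), so the
  nonzero-count detector misses ~2% of transduced cells.
* **Restoration** — 20% of planted DEGs are restorable; their per-vector
  improvement is 1.2 × Beta(5, 7) (mean 0.5, occasional overshoot), applied
  **only inside transgene-positive cells** by moving the planted mean back
  toward control. Kv8.2 action is cell-autonomous, and this choice plants
  exactly the dilution confounder the scoring stage must confront.

What the generator does **not** emulate: gene–gene correlation beyond cell
type, doublets, ambient RNA, batch effects beyond per-sample library size,
or realistic dropout curves. Passing recovery tests therefore demonstrates
that the pipeline's logic is correct under its stated model, not that any
specific biological dataset would yield the same numbers.

## Numerical and design choices

* The DE test is Wilcoxon rank-sum rather than a fitted count model: the
  downstream logic consumes only (significance, signed FC, group means), and
  the rank test is the robust default for single-cell comparisons. A
  model-based count fit would change p-values but not the pipeline contracts.
* Fold-change offset 0.01 CPM; α = 0.05 on BH-adjusted p; both configurable
  and recorded in every report.
* Kruskal–Wallis on fully tied data returns H = 0, p = 1 (the statistic's
  0/0 limit).
* PCA below-rank requests truncate with a warning rather than padding.
* Restoration truth for a simulated experiment is computed from the planted
  per-treatment improvements with the same ≥0.2/mode rule the estimator
  uses, so recovery error measures estimation, not rule mismatch.
* Test problem sizes: unit tests run reduced simulations (300–400 cells,
  ~300 genes); the recovery checks run 20 full-size seeds and the null
  calibration 200 reduced null datasets — sizes chosen to make Monte-Carlo
  bounds meaningful while keeping the suite quick on a laptop.

## Known limitations

* Cluster-level annotation caps accuracy when a cluster genuinely mixes
  types; per-cell scores are exposed for finer work.
* With a single disease genotype the "disease-model" DEG set is a
  single-contrast set; the run report flags this.
* The restored fraction is threshold-based, so genes near improvement 0.2
  flip classification under resampling; the recovery tolerance (±5
  percentage points MAE) accounts for this.
* Leiden clustering is deterministic only for a fixed seed and cell order.
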