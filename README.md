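# scpotency

Single-cell transcriptomic potency analysis of AAV gene-supplementation
vectors in retinal organoids.

In *KCNV2* retinopathy (cone dystrophy with supernormal rod response), loss of
the Kv8.2 potassium-channel subunit dysregulates photoreceptor gene
expression. One way to quantify how well an AAV vector carrying a
codon-optimised *KCNV2* transgene (driven by a photoreceptor-restricted RK
promoter or a ubiquitous CAG promoter) works is to ask: **of the genes that
go wrong in diseased rods and cones, how many does the vector pull back
toward control levels?** This package implements that question as a tested,
reusable scRNA-seq pipeline for anyone running organoid-based vector potency
studies:

1. **QC / normalisation** — cells with <500 UMIs, >20% mitochondrial or >20%
   ribosomal counts are excluded; expression is analysed as log2(CPM + 1).
2. **Cell-type annotation** — PCA on the top-100 variance features (7 PCs),
   Leiden clustering of the Euclidean kNN graph (k = 30), and an scType-style
   marker score assigning each cluster a retinal cell type.
3. **Transduction profiling** — a cell is transgene-positive at
   ≥ 1 × 10⁻⁴ CPM of the vector transcript (any nonzero UMI); percent
   positive and expression-in-positive are reported per sample × cell type.
4. **Disease-model DEGs** — per photoreceptor type, genes with BH-adjusted
   Wilcoxon p < α and signed fold change |FC| ≥ 1.2 in *both* the CRISPR-KO
   and patient contrasts, with concordant direction.
5. **Restoration scoring** — for each disease-model DEG with group-mean CPM
   `m_CON`, `m_KO`, `m_treated`, the improvement fraction is

   ```
   improvement = (m_treated − m_KO) / (m_CON − m_KO)
   ```

   and a gene is **restored** when improvement ≥ 0.2 (for both vectors by
   default, or either with `mode="any"`); a **full rescue** additionally
   requires treated expression to no longer differ significantly from
   control. The headline potency number is 100 × restored / total.
6. **Enrichment** — hypergeometric over-representation of DEG or
   restored-gene sets against user-supplied GMT collections.

Because studies of this kind rarely deposit raw data, the package ships a
first-class synthetic-data generator (`scpotency.simulate`) producing
organoid-like negative-binomial counts with planted cell types, disease
effects, promoter-specific transduction, and partial restoration — together
with the ground truth needed to verify every stage.

## Worked example

```python
from scpotency import PotencyAnalysis, SimConfig, AnalysisConfig
from scpotency.potency import RestorationConfig

cfg = AnalysisConfig(restoration=RestorationConfig(positives_only=True))
results = PotencyAnalysis.from_simulation(SimConfig(seed=1), cfg).fit()
print(results.summary())
```

```
Vector potency analysis
==============================================
cells: 7478/8000 pass QC; 8 clusters
mean composition (%): Rods 31.5, Cones 18.8, MullerGlia 12.7, Bipolar 10.1, Amacrine 7.8, Horizontal 7.5, Progenitors 6.8, Other 4.9
transgene-positive (% of sample): CON-1 0.0, KO-CAG 49.7, KO-NT 0.0, KO-RK 12.3
disease-model DEGs [Cones]: 204 (104 up, 100 down)
disease-model DEGs [Rods]: 204 (105 up, 99 down)
restored [Rods, KO]: 22.5% of disease-model DEGs
restored [Cones, KO]: 18.1% of disease-model DEGs
```

Reading this: 93% of simulated cells pass QC; the recovered composition
matches the planted organoid mix (rods ~31%, cones ~19%); the RK vector
transduces 12.3% of all cells (concentrated in photoreceptors) while CAG
reaches half of them; ~200 genes per photoreceptor type pass the significance
+ fold-change gates; and 22.5% of the rod disease genes move ≥20% back toward
control under both vectors — the potency read-out. `results.restoration`
holds the per-gene records, `results.save(outdir)` writes all tables as TSV,
and the `scpotency` CLI (`simulate`, `run`, `report` subcommands) drives the
same pipeline from a shell.

`positives_only=True` scores restoration on transgene-positive cells; with
the default all-cell means, partial transduction dilutes the measured
improvement by roughly the percent-positive — both modes are provided
because bulk-style group comparisons correspond to the all-cell reading.

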