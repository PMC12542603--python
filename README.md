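# chromastrat

Chromatin-structure-panel stratification of cardiac single-nucleus RNA-seq.

Chromatin remodellers and genome-topology regulators shape which genes a
cardiac cell can express, and their expression shifts in disease. This
package asks whether a curated panel of such chromatin-structural genes is,
by itself, enough to stratify cardiac cell populations by disease status —
the question behind comparing non-failing and dilated cardiomyopathy (DCM)
hearts at single-nucleus resolution. It is a library for computational
biologists who want to run, probe or extend that analysis, with every stage
testable against a synthetic cohort with planted ground truth.

## The method

The pipeline has two embedding stages built from the same chain:

1. **Stage 1 — cell typing.** Genes expressed in fewer than 1% of cells are
   temporarily filtered out; counts are scaled to the median library size
   and log1p-transformed; a three-layer autoencoder (input →
   10-dimensional embedded layer → reconstructed output, trained to
   minimize mean squared reconstruction error) compresses each cell to 10
   dimensions; UMAP lays the embedding out in 2-D and DBSCAN clusters it
   (noise label −1). Clusters are assigned a cell type by lineage markers
   (cardiomyocytes *ACTC1, MYH7, TNNT2, RYR2*; endothelium *PECAM1*; smooth
   muscle *GJC1, ACTA2*; macrophages *CD163*; lymphocytes *CD3E, CD3G,
   CD8A*; fibroblasts *COL1A1, FN1*), scoring each type as the mean
   across-cluster z-score of its markers' cluster means. Sex-biased genes
   (*XIST, UTY, KDM5D*) are excluded up front.
2. **Stage 2 — chromatin-panel stratification.** Within each cell type the
   matrix is restricted to the 892-gene chromatin-structure panel and the
   whole chain is re-run, yielding within-type subclusters (CM1, CM2, …,
   FB1, …; numbered by descending size).

Downstream of the clustering:

- **Markers.** A gene is an upregulated marker of a subcluster when
  (one-vs-rest Wilcoxon rank-sum) p < 10⁻⁶, it is expressed in ≥ 20% of
  in-cluster cells, and its mean abundance is ≥ 2-fold higher than in the
  other subclusters. Exact (permutation-null) and normal-approximation
  rank-sum modes are both provided.
- **Enrichment.** Marker lists are tested for over-representation in
  user-supplied GMT gene sets with a hypergeometric upper tail p = P[X ≥ k]
  computed in log space, Benjamini–Hochberg adjusted; results are kept when
  p < 0.01 or adjusted p < 0.05 and scored as −log₁₀(adjusted p).
- **Composition.** For each (cell type, condition), the percentage of that
  condition's cells in each subcluster — the stratification readout. On
  the cohort this package simulates, the disease-enriched cardiomyocyte
  subcluster holds ~18% of diseased and ~3% of healthy cardiomyocytes.

The synthetic cohort generator (`chromastrat.synthetic_cohort`) draws
negative-binomial counts with log-normal library sizes for six cardiac cell
types in two conditions and plants a cardiomyocyte subpopulation (3% of
healthy, 18% of diseased cardiomyocytes) whose ±1.5 log2FC signature lives
entirely on 40 panel genes, with full per-cell and per-gene truth labels
for recovery scoring (adjusted Rand index, marker sensitivity/precision,
exact binomial prevalence intervals).

The packaged panel (`data/chromatin_panel_synthetic.tsv`) is a synthetic
stand-in: a curated core of real human chromatin-regulator symbols padded
to exactly 892 with placeholder symbols; see its module docstring.

## A worked example

`examples/03_stratify_cardiomyocytes.py` generates a 4,000-cell cohort and
runs the stage-2 stratification of the cardiomyocytes:

```text
cardiomyocytes: 1971 cells -> 2 subclusters (+13 noise)
disease-enriched subcluster: CM2
  healthy :   3.3% of that condition's cardiomyocytes
  disease :  17.4% of that condition's cardiomyocytes
agreement with planted labels: ARI = 0.993
```

The two percentages recover the planted 3% / 18% prevalences from the raw
counts alone — the panel-restricted embedding found the planted
subpopulation — and the adjusted Rand index of 0.99 says the subcluster
boundaries nearly coincide with the planted labels. The other examples
cover simulation, stage-1 typing, marker selection, enrichment, and the
orchestrated end-to-end run (also available as the `chromastrat` command:
`simulate`, `run-all`, `embed`, `cluster`, `markers`, `enrich`, `compose`,
`evaluate`).

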