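"""Stage-1 embedding and cell typing on a small synthetic cohort.

Filters rare genes, normalizes, trains the 10-dimensional autoencoder,
projects with UMAP, clusters with DBSCAN, and assigns cell types from
lineage markers (ACTC1/MYH7/TNNT2/RYR2 for cardiomyocytes, PECAM1 for
endothelium, ...), then compares against the planted types.
"""

import numpy as np

from chromastrat import default_config, generate_cohort
from chromastrat.clustering import StageParams, assign_cell_types, embed_project_cluster
from chromastrat.synthetic_cohort import DEFAULT_MARKER_MAP

cfg = default_config(n_cells_per_condition=600, seed=7)
matrix, annotation, _ = generate_cohort(cfg)

labels, embedding, projection, norm = embed_project_cluster(
    matrix, StageParams(seed=0, umap_neighbors=20))
print(f"embedded {embedding.values.shape[0]} cells into "
      f"{embedding.values.shape[1]} dims; DBSCAN found "
      f"{labels.n_clusters} clusters (+{labels.n_noise} noise cells, eps={labels.eps:.3f})")

assignment = assign_cell_types(norm, labels, DEFAULT_MARKER_MAP)
truth_types = annotation.column("cell_type")
for cid in labels.cluster_ids():
    members = truth_types[labels.labels == cid]
    purity = np.mean(members == assignment.types[cid])
    print(f"  cluster {cid}: n={members.size:4d} -> {assignment.types[cid]:<14s}"
          f" (marker-score margin {assignment.margins[cid]:.2f}, "
          f"planted-type purity {100 * purity:.0f}%)")
# The dominant lineages (cardiomyocyte, fibroblast) separate cleanly; rare
# types that differ by a single marker gene can merge into a mixed cluster —
# real lineages differ in many more genes than this minimal simulation.
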