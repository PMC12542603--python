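"""Three-criterion marker selection for the disease-enriched subcluster.

Markers are genes with Wilcoxon rank-sum p < 1e-6, expressed in >= 20% of
in-cluster cells, and >= 2-fold mean elevation over the other subclusters.
On synthetic data the selected genes can be scored against the planted
signature.
"""

import numpy as np

from chromastrat import default_config, generate_cohort, packaged_panel
from chromastrat.clustering import StageParams, subcluster_by_type
from chromastrat.embedding import normalize
from chromastrat.evaluation import composition, disease_enriched_subcluster, marker_recovery
from chromastrat.markers import MarkerCriteria, select_markers

cfg = default_config(n_cells_per_condition=2000, seed=1)
matrix, annotation, truth = generate_cohort(cfg)
results = subcluster_by_type(matrix, annotation, packaged_panel(),
                             StageParams(seed=1), cell_types=["cardiomyocyte"])
labels = results["cardiomyocyte"].labels

# marker tests run on the full gene set (the rare-gene filter is temporary)
cm_cells = np.flatnonzero(annotation.column("cell_type") == "cardiomyocyte")
norm = normalize(matrix.subset_cells(cm_cells))
records = select_markers(norm, labels, MarkerCriteria())

comp = composition({"cardiomyocyte": labels}, annotation)
target = disease_enriched_subcluster(comp, "cardiomyocyte")
hits = [r for r in records if r.cluster == target]
print(f"subcluster {target}: {len(hits)} upregulated markers")
for r in hits[:5]:
    print(f"  {r.gene:<10s} p={r.p_value:.2e} fraction_in={r.fraction_in:.2f} "
          f"log2FC={r.log2fc:+.2f}")

sens, prec = marker_recovery(records, truth, target)
print(f"against the planted +1.5 log2FC genes: sensitivity={sens:.2f}, precision={prec:.2f}")
# log2FC near +1.5 is the planted effect size; sensitivity/precision of 1.0
# mean the criteria recover exactly the planted upregulated panel genes.
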