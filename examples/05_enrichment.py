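"""Over-representation analysis of a marker list against GMT gene sets.

Builds a small gene-set collection over the panel, queries it with a gene
list overlapping one set, and prints the hypergeometric p-values, the
Benjamini-Hochberg adjustment, and the enrichment score (-log10 adjusted p).
"""

from chromastrat import packaged_panel
from chromastrat.enrichment import GeneSetCollection, enrich

panel = sorted(packaged_panel().symbols)
universe = panel  # in a pipeline run: all genes surviving the rare-gene filter

collection = GeneSetCollection({
    "chromatin_remodelling": frozenset(panel[0:60]),
    "histone_modification": frozenset(panel[60:120]),
    "genome_topology": frozenset(panel[120:180]),
    "nuclear_lamina": frozenset(panel[180:240]),
})

query = panel[0:25] + panel[300:310]  # 25 genes of one set + 10 background
records = enrich(query, collection, universe)

print(f"query of {len(query)} genes against {len(collection)} sets "
      f"(universe {len(universe)}):")
for r in records:
    print(f"  {r.term:<22s} k={r.k:>2d}/K={r.K} p={r.p_value:.3e} "
          f"adj={r.p_adjusted:.3e} score={r.enrichment_score:.1f}")
# Only terms passing the p < 0.01 or adjusted p < 0.05 filter are returned;
# the score is -log10 of the adjusted p, so bigger means more enriched.
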