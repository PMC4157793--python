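"""Discover expression subtypes by resampling consensus clustering.

Generates a cohort with three planted expression subtypes, z-scores the
probe-collapsed matrix, runs consensus clustering over K = 2..10
(250 resamples at 80% subsampling), and prints the per-K diagnostics, the
chosen K, and how well the labels recover the planted subtypes.
"""

from sklearn.metrics import adjusted_rand_score

from pharmsig import collapse_probes, consensus_cluster, standard_normalize, subtype_markers
from pharmsig.simulate import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(seed=7))
gene = collapse_probes(cohort.probe_matrix, cohort.probe_gene_map)
z = standard_normalize(gene)

result = consensus_cluster(z, maxk=10, resamples=250, seed=7)
print(" K   CDF-area  rel-delta  ambiguous")
for k in sorted(result.areas):
    print(f"{k:>2}   {result.areas[k]:>8.3f}  {result.delta_areas[k]:>9.3f}"
          f"  {result.pac[k]:>9.3f}")
print(f"\nchosen K = {result.chosen_k}")

truth = [cohort.truth.subtype[c] for c in z.col_ids]
labels = [result.labels[c] for c in z.col_ids]
print(f"adjusted Rand vs planted subtypes = "
      f"{adjusted_rand_score(truth, labels):.3f}")

markers = subtype_markers(z, result.labels, alpha=0.05)
print(f"{len(markers.selected_genes)} subtype-marker genes at "
      f"Kruskal-Wallis p < 0.05 (600 planted)")
# A crisp consensus at K = 2 and 3 with ambiguity appearing at K = 4
# marks three reproducible subtypes; the Rand index near 1 means the
# labels match the planted subtypes almost exactly.
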