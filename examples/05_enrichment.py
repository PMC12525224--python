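"""Gene-set enrichment of a target list, with the disease-pathway whitelist.

A toy GMT library stands in for KEGG: each term's one-sided hypergeometric
p-value, BH-adjusted p, odds ratio and rank-deviation z/combined score are
computed, then the hyperthyroidism-associated signaling pathways are
filtered out of the full result list.
"""

from herbwalk.enrichment import enrich, filter_disease_pathways, results_to_frame

background = {f"G{i:02d}" for i in range(40)}
library = {
    "MAPK signaling pathway": {f"G{i:02d}" for i in range(0, 10)},
    "Thyroid hormone signaling pathway": {f"G{i:02d}" for i in range(5, 13)},
    "PI3K-Akt signaling pathway": {f"G{i:02d}" for i in range(8, 20)},
    "Ribosome": {f"G{i:02d}" for i in range(20, 32)},
    "Spliceosome": {f"G{i:02d}" for i in range(30, 40)},
}
query = {f"G{i:02d}" for i in range(0, 9)}  # mostly MAPK/thyroid members

results = enrich(query, library, background, n_background_queries=200, seed=0)
print(results_to_frame(results).to_string(index=False))

kept = filter_disease_pathways(results)
print("\ndisease-pathway whitelist hits:")
for r in kept:
    print(f"  {r.term}: p={r.p_value:.2e}, adjusted={r.adjusted_p:.2e}, "
          f"combined={r.combined_score:.1f}")
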