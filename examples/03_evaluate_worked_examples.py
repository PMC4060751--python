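"""Score published candidate lists against their benchmarks.

Reproduces three reference computations: recall of the 46-gene headache and
83-gene hemiplegia candidate lists against their curated benchmark sets, and
the muscle-cramp fold-enrichment arithmetic over random gene selection.
"""

from symgene import fold_enrichment, recall_in_list
from symgene.worked_examples import (
    HEADACHE_TOP46,
    HEMIPLEGIA_TOP83,
    MUSCLE_CRAMP_ENRICHMENT,
    headache_benchmark,
    hemiplegia_benchmark,
)

r_head = recall_in_list([g for g, _ in HEADACHE_TOP46], headache_benchmark())
r_hemi = recall_in_list([g for g, _ in HEMIPLEGIA_TOP83], hemiplegia_benchmark())
print(f"headache   recall: {r_head:.2f}%  (2 of 32 benchmark genes in the 46-gene list)")
print(f"hemiplegia recall: {r_hemi:.1f}%  (4 of 6 benchmark genes in the 83-gene list)")

e = fold_enrichment(**MUSCLE_CRAMP_ENRICHMENT)
print(f"muscle cramp: per-gene probability {e.per_gene_prob:.7f}, "
      f"expected overlap {e.expected:.3f}, observed {e.observed}")
print(f"  -> {e.fold:.1f}-fold enrichment over random selection")
print()
print("Recall measures how much of the curated benchmark the candidate list\n"
      "recovers; fold enrichment compares the observed benchmark hits with the\n"
      "hypergeometric expectation for a random list of the same size.")
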