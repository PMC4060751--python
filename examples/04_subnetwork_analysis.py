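"""Classify benchmark genes relative to the causal genes of a disease set.

Given the diseases most related to a symptom, a benchmark gene is "explained"
by the subnetwork if it is itself a causal gene of one of the diseases, or if
it lies on an unweighted shortest path between two causal genes in the PPI.
"""

from symgene import PhenoGenoNetwork, disease_subnetwork

edges = {
    ("TNFA", "LINK1"), ("LINK1", "EDN1"),          # path between causal genes
    ("TNFA", "CALC"), ("EDN1", "CALC"),            # alternative shortest path
    ("EDN1", "FAR1"), ("FAR1", "FAR2"),            # periphery
}
disease_genes = {"migraine": {"TNFA", "EDN1"}, "tension": {"CALC"}}
net = PhenoGenoNetwork.from_edges(edges, disease_genes)

benchmark = {"TNFA", "LINK1", "FAR2"}
rep = disease_subnetwork(net, {"migraine", "tension"}, benchmark)

print("causal genes:         ", sorted(rep.causal_genes))
print("on a shortest path:   ", sorted(rep.shortest_path_genes))
print("benchmark as causal:  ", sorted(rep.benchmark_causal))
print("benchmark on path:    ", sorted(rep.benchmark_on_path))
print("benchmark explained:  ", sorted(rep.benchmark_explained))
print()
print("TNFA is explained as a causal gene, LINK1 because it sits on a shortest\n"
      "path between the causal genes TNFA and EDN1; FAR2 is neither.")
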