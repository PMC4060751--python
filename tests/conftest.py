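import numpy as np
import pytest

from symgene.cooccurrence import RecordCorpus
from symgene.network import PhenoGenoNetwork


def random_corpus(rng, n_records=50, n_symptoms=6, n_diseases=4):
    """A small random corpus with explicit vocabularies."""
    symptoms = [f"s{i}" for i in range(n_symptoms)]
    diseases = [f"d{i}" for i in range(n_diseases)]
    records = []
    for r in range(n_records):
        syms = {s for s in symptoms if rng.random() < 0.4}
        dis = {d for d in diseases if rng.random() < 0.3}
        records.append((f"r{r}", syms, dis))
    return RecordCorpus.from_records(records, symptoms, diseases)


def random_network(rng, n_nodes=30, p_edge=0.15):
    """A random undirected unit-weight PPI with at least one edge."""
    genes = [f"g{i:02d}" for i in range(n_nodes)]
    edges = set()
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                edges.add((genes[i], genes[j]))
    if not edges:
        edges.add((genes[0], genes[1]))
    return PhenoGenoNetwork.from_edges(edges, {})


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_net():
    """Path a-b-c-d plus a pendant e on b, with two diseases."""
    edges = {("a", "b"), ("b", "c"), ("c", "d"), ("b", "e")}
    dg = {"dis1": {"A", "B"}, "dis2": {"D"}, "dis_empty": set()}
    return PhenoGenoNetwork.from_edges(edges, dg)
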