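"""Per-symptom prior over network genes.

The prior Y : V -> [0,1] seeds the propagation.  Diseases are first filtered
by a global similarity cutoff: among all symptom-disease pairs with cosine
similarity above ``min_similarity`` (default 0.1), the top ``top_fraction``
(default 10%) are kept; the cutoff is the smallest similarity such that at
least that fraction of the pool is >= it (closed upper tail, no
interpolation).  For a query symptom, the ``top_k_diseases`` (default 10)
most similar above-cutoff diseases are selected and Y assigns 1 to every
network gene associated with any of them, 0 elsewhere.

A similarity-weighted variant (Y[g] = max similarity over the selected
diseases carrying g) is available via ``weighted=True`` but is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .cooccurrence import SimilarityTable
from .network import PhenoGenoNetwork

__all__ = [
    "PriorConfig",
    "PriorVector",
    "similarity_cutoff",
    "select_diseases",
    "build_prior",
    "EmptyPriorPoolError",
    "UnknownSymptomError",
    "NoSeedGenesError",
]


class EmptyPriorPoolError(ValueError):
    """No symptom-disease pair exceeds the minimum similarity."""


class UnknownSymptomError(KeyError):
    """The query symptom has no entry in the similarity table."""


class NoSeedGenesError(ValueError):
    """No gene of the selected diseases is present in the PPI network."""


@dataclass(frozen=True)
class PriorConfig:
    """Disease-selection parameters for building the prior.

    min_similarity : similarity floor for the candidate pool (default 0.1)
    top_fraction   : fraction of the above-floor pool kept (default 0.10)
    top_k_diseases : diseases retained per symptom (default 10)
    scope          : 'global' computes one cutoff over all pairs;
                     'per-symptom' computes it within each symptom's pairs
    weighted       : similarity-weighted Y instead of binary
    """

    min_similarity: float = 0.1
    top_fraction: float = 0.10
    top_k_diseases: int = 10
    scope: Literal["global", "per-symptom"] = "global"
    weighted: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.top_k_diseases < 1:
            raise ValueError("top_k_diseases must be >= 1")
        if self.min_similarity < 0:
            raise ValueError("min_similarity must be >= 0")


@dataclass
class PriorVector:
    """Prior knowledge vector Y over the PPI node order.

    ``supporting_diseases`` lists the selected (disease, similarity) pairs,
    most similar first; ``missing_genes`` are disease genes absent from the
    network (reported, not seeded).
    """

    symptom: str
    values: np.ndarray
    nodes: tuple[str, ...]
    supporting_diseases: list[tuple[str, float]]
    missing_genes: set[str] = field(default_factory=set)

    def seed_genes(self) -> set[str]:
        return {g for g, v in zip(self.nodes, self.values) if v > 0}


def similarity_cutoff(table: SimilarityTable, cfg: PriorConfig) -> float:
    """Similarity value delimiting the top ``top_fraction`` of the pool.

    The pool is every entry with similarity strictly above
    ``cfg.min_similarity``; entries at exactly the returned cutoff are kept
    by downstream selection.
    """
    if not len(table):
        raise ValueError("similarity table is empty")
    pool = sorted(
        (v for v in table.entries.values() if v > cfg.min_similarity), reverse=True
    )
    if not pool:
        raise EmptyPriorPoolError(
            f"no similarity exceeds min_similarity={cfg.min_similarity}"
        )
    k = int(np.ceil(cfg.top_fraction * len(pool)))
    return pool[k - 1]


def select_diseases(
    symptom: str, table: SimilarityTable, cutoff: float, cfg: PriorConfig
) -> list[tuple[str, float]]:
    """The most related diseases for a symptom.

    Diseases with similarity >= cutoff, sorted by similarity descending then
    disease id ascending, truncated to ``top_k_diseases``; fewer may be
    returned.
    """
    pairs = table.pairs_for_symptom(symptom)
    if not pairs:
        raise UnknownSymptomError(symptom)
    qualifying = [(d, v) for d, v in pairs if v >= cutoff]
    qualifying.sort(key=lambda dv: (-dv[1], dv[0]))
    return qualifying[: cfg.top_k_diseases]


def build_prior(
    symptom: str,
    diseases: list[tuple[str, float]],
    net: PhenoGenoNetwork,
    weighted: bool = False,
) -> PriorVector:
    """Assemble Y from the selected diseases' causal genes.

    Binary mode sets Y[g] = 1 for every gene associated with a selected
    disease and present in V; weighted mode uses the maximum similarity among
    the selected diseases carrying the gene.  Genes associated but absent
    from V are returned in ``missing_genes``.
    """
    if not diseases:
        raise ValueError("no diseases selected for prior")
    index = net.node_index
    values = np.zeros(len(net.ppi_nodes))
    missing: set[str] = set()
    for disease, sim in diseases:
        for gene in net.disease_genes.get(disease, set()):
            i = index.get(gene)
            if i is None:
                missing.add(gene)
            elif weighted:
                values[i] = max(values[i], sim)
            else:
                values[i] = 1.0
    if not values.any():
        raise NoSeedGenesError(
            f"symptom {symptom!r}: no gene of the selected diseases is in the network"
        )
    return PriorVector(symptom, values, tuple(net.ppi_nodes), list(diseases), missing)
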