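"""Heterogeneous phenotype-genotype network assembly.

Combines a disease->gene association map (B) with an undirected PPI graph
G = (V, E).  The PPI adjacency W is symmetric with zero diagonal and unit
default edge weights.  For propagation W is rescaled to the degree-symmetric
normalization

    W'[i, j] = W[i, j] / sqrt(deg(i) * deg(j)),

whose spectral radius is at most 1, guaranteeing convergence of the
propagation update for alpha < 1.  A row-stochastic alternative
(W'[i, j] = W[i, j] / deg(i)) is available via ``method``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import networkx as nx
import numpy as np
from scipy import sparse

__all__ = [
    "PhenoGenoNetwork",
    "NormalizedAdjacency",
    "load_network",
    "normalize_adjacency",
    "disease_subnetwork",
    "SubnetworkReport",
]

logger = logging.getLogger(__name__)


def _canon(identifier: str) -> str:
    """Trim and upper-case an identifier (matching is case-insensitive)."""
    return identifier.strip().upper()


@dataclass
class PhenoGenoNetwork:
    """Disease-gene map plus undirected PPI graph with adjacency matrix.

    Attributes
    ----------
    disease_genes
        Mapping disease -> set of associated genes (including genes absent
        from the PPI; those are additionally listed in ``orphan_genes``).
    ppi_nodes
        Deterministic (sorted) node order V; indexes the adjacency rows.
    ppi_edges
        Set of ``(gene_a, gene_b, weight)`` with ``gene_a < gene_b``.
    adjacency
        |V| x |V| symmetric CSR matrix W with zero diagonal.
    orphan_genes
        Disease-associated genes not present in the PPI, per disease.
    """

    disease_genes: dict[str, set[str]]
    ppi_nodes: list[str]
    ppi_edges: set[tuple[str, str, float]]
    adjacency: sparse.csr_matrix
    orphan_genes: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = self.adjacency
        if (abs(W - W.T) > 1e-12).nnz:
            raise ValueError("adjacency must be symmetric")
        if np.any(W.diagonal() != 0):
            raise ValueError("adjacency diagonal must be zero")

    @property
    def node_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.ppi_nodes)}

    @classmethod
    def from_edges(
        cls,
        edges: "set[tuple[str, str]] | set[tuple[str, str, float]] | list",
        disease_genes: dict[str, set[str]],
    ) -> "PhenoGenoNetwork":
        """Build a network from in-memory edges (weight defaults to 1)."""
        collapsed: dict[tuple[str, str], float] = {}
        for e in edges:
            a, b = _canon(e[0]), _canon(e[1])
            w = float(e[2]) if len(e) == 3 else 1.0
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            collapsed.setdefault(key, w)
        nodes = sorted({g for pair in collapsed for g in pair})
        index = {g: i for i, g in enumerate(nodes)}
        ii = [index[a] for a, _ in collapsed]
        jj = [index[b] for _, b in collapsed]
        ww = list(collapsed.values())
        W = sparse.coo_matrix(
            (ww + ww, (ii + jj, jj + ii)), shape=(len(nodes), len(nodes))
        ).tocsr()
        dg = {d: {_canon(g) for g in gs} for d, gs in disease_genes.items()}
        node_set = set(nodes)
        orphan = {
            d: {g for g in gs if g not in node_set}
            for d, gs in dg.items()
            if any(g not in node_set for g in gs)
        }
        edge_set = {(a, b, w) for (a, b), w in collapsed.items()}
        return cls(dg, nodes, edge_set, W, orphan)

    def graph(self) -> nx.Graph:
        """The PPI as a networkx graph (weights as edge attributes)."""
        g = nx.Graph()
        g.add_nodes_from(self.ppi_nodes)
        g.add_weighted_edges_from(self.ppi_edges)
        return g

    def genes_of(self, diseases: set[str] | list[str]) -> set[str]:
        """Union of associated genes over the given diseases."""
        out: set[str] = set()
        for d in diseases:
            out |= self.disease_genes.get(d, set())
        return out


def _parse_tsv(path: str | Path, min_fields: int, max_fields: int) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if not (min_fields <= len(parts) <= max_fields):
                raise ValueError(
                    f"{path}: line {lineno}: expected {min_fields}-{max_fields} "
                    f"tab-separated fields, got {len(parts)}"
                )
            if any(not p for p in parts[:min_fields]):
                raise ValueError(f"{path}: line {lineno}: empty identifier")
            rows.append((lineno, parts))
    return rows


def load_network(
    ppi_file: str | Path, disease_gene_file: str | Path
) -> PhenoGenoNetwork:
    """Load a PPI edge list and a disease-gene table into one network.

    PPI file: ``gene_a TAB gene_b [TAB weight]``.  Duplicate edges (in either
    orientation) are collapsed keeping the first weight seen; self-loops are
    dropped with a logged count.  Disease-gene file: ``disease TAB gene``;
    rows whose gene is absent from the PPI are retained but flagged in
    ``orphan_genes``.  Gene identifiers are matched case-insensitively after
    trimming.
    """
    edges: dict[tuple[str, str], float] = {}
    self_loops = 0
    header_tokens = {"GENE_A", "GENE_B", "GENE1", "GENE2", "SOURCE", "TARGET"}
    for lineno, parts in _parse_tsv(ppi_file, 2, 3):
        a, b = _canon(parts[0]), _canon(parts[1])
        if lineno == 1 and a in header_tokens:
            continue
        if len(parts) == 3:
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{ppi_file}: line {lineno}: bad weight {parts[2]!r}") from exc
        else:
            w = 1.0
        if w < 0:
            raise ValueError(f"{ppi_file}: line {lineno}: negative weight")
        if a == b:
            self_loops += 1
            continue
        key = (a, b) if a < b else (b, a)
        edges.setdefault(key, w)
    if self_loops:
        logger.warning("dropped %d self-loop(s) from %s", self_loops, ppi_file)

    nodes = sorted({g for pair in edges for g in pair})
    index = {g: i for i, g in enumerate(nodes)}
    if edges:
        ii = [index[a] for a, _ in edges]
        jj = [index[b] for _, b in edges]
        ww = list(edges.values())
        W = sparse.coo_matrix(
            (ww + ww, (ii + jj, jj + ii)), shape=(len(nodes), len(nodes))
        ).tocsr()
    else:
        W = sparse.csr_matrix((0, 0))

    disease_genes: dict[str, set[str]] = {}
    orphan: dict[str, set[str]] = {}
    node_set = set(nodes)
    for lineno, parts in _parse_tsv(disease_gene_file, 2, 2):
        if lineno == 1 and parts[0].strip().lower() == "disease":
            continue
        disease, gene = parts[0], _canon(parts[1])
        disease_genes.setdefault(disease, set()).add(gene)
        if gene not in node_set:
            orphan.setdefault(disease, set()).add(gene)
    if orphan:
        n_flagged = sum(len(v) for v in orphan.values())
        logger.warning(
            "%d disease-gene association(s) reference genes absent from the PPI", n_flagged
        )

    edge_set = {(a, b, w) for (a, b), w in edges.items()}
    return PhenoGenoNetwork(disease_genes, nodes, edge_set, W, orphan)


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Degree-normalized adjacency W' used by the propagation update."""

    matrix: sparse.csr_matrix
    nodes: tuple[str, ...]
    method: Literal["symmetric", "row-stochastic"] = "symmetric"


def normalize_adjacency(
    net: PhenoGenoNetwork, method: Literal["symmetric", "row-stochastic"] = "symmetric"
) -> NormalizedAdjacency:
    """Rescale W by weighted node degrees.

    ``symmetric``: W'[i,j] = W[i,j] / sqrt(deg(i) deg(j)) — symmetric, spectral
    radius <= 1.  ``row-stochastic``: W'[i,j] = W[i,j] / deg(i).  Rows and
    columns of isolated nodes are zero in both cases.
    """
    W = net.adjacency.astype(float)
    if W.nnz == 0:
        raise ValueError("network has no edges")
    deg = np.asarray(W.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv = 1.0 / deg
        inv_sqrt = 1.0 / np.sqrt(deg)
    inv[~np.isfinite(inv)] = 0.0
    inv_sqrt[~np.isfinite(inv_sqrt)] = 0.0
    if method == "symmetric":
        D = sparse.diags(inv_sqrt)
        Wn = D @ W @ D
    elif method == "row-stochastic":
        Wn = sparse.diags(inv) @ W
    else:
        raise ValueError(f"unknown normalization {method!r}")
    return NormalizedAdjacency(Wn.tocsr(), tuple(net.ppi_nodes), method)


@dataclass
class SubnetworkReport:
    """Where benchmark genes sit relative to the causal genes of a disease set."""

    causal_genes: set[str]                 # category (i): causal genes of the diseases
    shortest_path_genes: set[str]          # category (ii): on a shortest path between causal genes
    benchmark_causal: set[str]             # benchmark genes that are causal
    benchmark_on_path: set[str]            # benchmark genes on a shortest path (not causal)
    skipped_diseases: list[str]            # diseases contributing no genes

    @property
    def benchmark_explained(self) -> set[str]:
        return self.benchmark_causal | self.benchmark_on_path


def disease_subnetwork(
    net: PhenoGenoNetwork, diseases: set[str], benchmark_genes: set[str]
) -> SubnetworkReport:
    """Classify benchmark genes as causal genes of the diseases or as lying on
    an (unweighted) shortest path between two causal genes.

    A node x lies on a shortest path between causal genes a and b iff
    d(a, x) + d(x, b) = d(a, b).  Pairs in different connected components
    contribute nothing.
    """
    missing = [d for d in diseases if d not in net.disease_genes]
    if missing:
        raise KeyError(f"disease(s) not in association table: {sorted(missing)}")
    skipped = sorted(d for d in diseases if not net.disease_genes.get(d))
    for d in skipped:
        logger.warning("disease %r has no associated genes; skipped", d)

    causal = {g for d in diseases for g in net.disease_genes.get(d, set())}
    g = net.graph()
    anchors = sorted(causal & set(net.ppi_nodes))

    # d(a, .) for every causal anchor; x on a shortest a-b path iff
    # dist[a][x] + dist[b][x] == dist[a][b]
    dist = {a: nx.single_source_shortest_path_length(g, a) for a in anchors}
    on_path: set[str] = set()
    for i, a in enumerate(anchors):
        da = dist[a]
        for b in anchors[i + 1 :]:
            db = dist[b]
            if b not in da:
                continue  # different components
            dab = da[b]
            for x, dax in da.items():
                if dax <= dab and db.get(x, dab + 1) + dax == dab:
                    on_path.add(x)
    on_path -= causal

    bench_causal = benchmark_genes & causal
    bench_path = benchmark_genes & on_path
    return SubnetworkReport(causal, on_path, bench_causal, bench_path, skipped)
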