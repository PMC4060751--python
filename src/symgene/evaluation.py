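"""Evaluation of ranked gene lists against a benchmark gene set.

Three complementary measures:

* recall — percentage of benchmark genes recovered in a candidate list;
* AUC — probability that a random benchmark gene outscores a random
  non-benchmark gene (Mann-Whitney statistic; ties count 1/2).  Negatives are
  all scored network genes outside the benchmark;
* fold enrichment — benchmark hits observed in a selected list of size k,
  divided by the expectation k * |benchmark| / |universe| under uniformly
  random selection (the hypergeometric mean).

Reports round the per-gene probability to 7 decimals and the expected
overlap to 3, the precision these quantities are customarily printed at.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .propagation import PropagationConfig, ScoreVector, potential_genes, rank_genes

__all__ = [
    "BenchmarkSet",
    "Enrichment",
    "EvaluationReport",
    "recall_in_list",
    "rank_auc",
    "pooled_auc",
    "fold_enrichment",
    "monte_carlo_expected_overlap",
    "evaluate_symptom",
    "read_benchmark",
]


@dataclass(frozen=True)
class BenchmarkSet:
    """Curated symptom -> gene associations for one symptom."""

    symptom: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"benchmark for {self.symptom!r} is empty")


def read_benchmark(path: str | Path) -> dict[str, BenchmarkSet]:
    """Read a TSV of ``symptom TAB gene`` pairs into per-symptom sets."""
    df = pd.read_csv(path, sep="\t", names=["symptom", "gene"], header=None, dtype=str)
    if df.iloc[0, 0] == "symptom":
        df = df.iloc[1:]
    out: dict[str, set[str]] = {}
    for row in df.itertuples():
        out.setdefault(row.symptom, set()).add(row.gene.strip().upper())
    return {s: BenchmarkSet(s, frozenset(g)) for s, g in out.items()}


def recall_in_list(genes: Iterable[str], benchmark: BenchmarkSet) -> float:
    """100 * |list ∩ benchmark| / |benchmark| (the list may be ranked tuples)."""
    names = {g[0] if isinstance(g, tuple) else g for g in genes}
    return 100.0 * len(names & benchmark.genes) / len(benchmark.genes)


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC via midranks; ties between classes contribute 1/2."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    n_pos, n_neg = len(pos), len(neg)
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def rank_auc(F: ScoreVector, benchmark: BenchmarkSet) -> float:
    """AUC of the score ordering: positives = benchmark ∩ V, negatives = V \\ benchmark."""
    labels = np.array([g in benchmark.genes for g in F.nodes])
    if not labels.any():
        raise ValueError(
            f"benchmark for {benchmark.symptom!r} is disjoint from the network"
        )
    if labels.all():
        raise ValueError("no negative genes: benchmark covers the whole network")
    return _mann_whitney_auc(F.scores[labels], F.scores[~labels])


def pooled_auc(
    results: Sequence[tuple[ScoreVector, BenchmarkSet]], mode: str = "pooled"
) -> float:
    """AUC over several symptoms.

    ``pooled`` concatenates every (score, label) pair across symptoms into one
    Mann-Whitney statistic (the default); ``mean`` averages per-symptom AUCs,
    skipping symptoms whose benchmark misses the network.
    """
    if mode == "mean":
        aucs = []
        for F, bench in results:
            try:
                aucs.append(rank_auc(F, bench))
            except ValueError:
                continue
        if not aucs:
            raise ValueError("no symptom had benchmark genes in the network")
        return float(np.mean(aucs))
    pos, neg = [], []
    for F, bench in results:
        labels = np.array([g in bench.genes for g in F.nodes])
        pos.append(F.scores[labels])
        neg.append(F.scores[~labels])
    pos_all, neg_all = np.concatenate(pos), np.concatenate(neg)
    if len(pos_all) == 0 or len(neg_all) == 0:
        raise ValueError("pooled evaluation needs both positives and negatives")
    return _mann_whitney_auc(pos_all, neg_all)


@dataclass(frozen=True)
class Enrichment:
    """Observed versus random-expected benchmark hits in a k-gene selection."""

    k: int
    observed: int
    per_gene_prob: float
    expected: float
    fold: float


def fold_enrichment(
    observed: int, k: int, benchmark_size: int, universe_size: int
) -> Enrichment:
    """Fold enrichment of an observed hit count over random gene selection.

    per_gene_prob = benchmark_size / universe_size; expected = per_gene_prob * k
    (the hypergeometric mean); fold = observed / expected.
    """
    if universe_size <= 0:
        raise ValueError("universe_size must be positive")
    if k > universe_size:
        raise ValueError("selected list larger than the gene universe")
    if not (0 <= observed <= min(k, benchmark_size)):
        raise ValueError("observed count outside feasible range")
    p = benchmark_size / universe_size
    expected = p * k
    fold = observed / expected if expected > 0 else 0.0
    return Enrichment(k, observed, p, expected, fold)


def monte_carlo_expected_overlap(
    k: int,
    benchmark_size: int,
    universe_size: int,
    n_draws: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mean and standard error of benchmark hits over random k-gene draws.

    Cross-checks the analytic hypergeometric expectation by simulation.
    """
    rng = rng if rng is not None else np.random.default_rng()
    hits = stats.hypergeom.rvs(
        universe_size, benchmark_size, k, size=n_draws, random_state=rng
    )
    return float(hits.mean()), float(hits.std(ddof=1) / np.sqrt(n_draws))


@dataclass
class EvaluationReport:
    """Recall, AUC and fold enrichment for one symptom's ranking."""

    symptom: str
    recall_at_list: float
    auc: float | None
    enrichment: Enrichment
    n_unscored: int = 0

    def to_dict(self) -> dict:
        e = self.enrichment
        return {
            "symptom": self.symptom,
            "recall_at_list": self.recall_at_list,
            "auc": self.auc,
            "enrichment": {
                "k": e.k,
                "observed": e.observed,
                "per_gene_prob": round(e.per_gene_prob, 7),
                "expected": round(e.expected, 3),
                "fold": e.fold,
            },
            "n_unscored": self.n_unscored,
        }


def evaluate_symptom(
    F: ScoreVector,
    benchmark: BenchmarkSet,
    cfg: PropagationConfig = PropagationConfig(),
) -> EvaluationReport:
    """Bundle the three metrics for one symptom.

    The candidate list for recall and enrichment is the potential-gene list
    (scores strictly above the cutoff).  AUC is None when the benchmark is
    disjoint from the network; benchmark genes without a score are counted in
    ``n_unscored``.
    """
    ranked = rank_genes(F)
    candidates = potential_genes(ranked, cfg)
    names = {g for g, _, _ in candidates}
    observed = len(names & benchmark.genes)
    enr = fold_enrichment(
        observed,
        len(candidates),
        benchmark_size=len(benchmark.genes),
        universe_size=len(F.nodes),
    ) if candidates else Enrichment(0, 0, len(benchmark.genes) / len(F.nodes), 0.0, 0.0)
    try:
        auc = rank_auc(F, benchmark)
    except ValueError:
        auc = None
    n_unscored = len(benchmark.genes - set(F.nodes))
    return EvaluationReport(
        F.symptom, recall_in_list(names, benchmark), auc, enr, n_unscored
    )
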