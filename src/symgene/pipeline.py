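"""End-to-end orchestration: similarity -> prior -> propagation -> evaluation."""

from __future__ import annotations

from dataclasses import dataclass

from .cooccurrence import RecordCorpus, SimilarityTable, build_similarity_table
from .evaluation import BenchmarkSet, EvaluationReport, evaluate_symptom, pooled_auc
from .network import NormalizedAdjacency, PhenoGenoNetwork, normalize_adjacency
from .prior import (
    NoSeedGenesError,
    PriorConfig,
    UnknownSymptomError,
    build_prior,
    select_diseases,
    similarity_cutoff,
)
from .propagation import PropagationConfig, ScoreVector, propagate

__all__ = ["prioritize_symptom", "PipelineResult", "run_pipeline"]


def prioritize_symptom(
    symptom: str,
    table: SimilarityTable,
    net: PhenoGenoNetwork,
    prior_cfg: PriorConfig = PriorConfig(),
    prop_cfg: PropagationConfig = PropagationConfig(),
    Wn: NormalizedAdjacency | None = None,
    cutoff: float | None = None,
) -> ScoreVector:
    """Rank all network genes for one query symptom.

    ``Wn`` and ``cutoff`` may be precomputed once when scoring many symptoms
    against the same network and similarity table.
    """
    if cutoff is None:
        cutoff = similarity_cutoff(table, prior_cfg)
    if Wn is None:
        Wn = normalize_adjacency(net)
    diseases = select_diseases(symptom, table, cutoff, prior_cfg)
    if not diseases:
        raise NoSeedGenesError(f"symptom {symptom!r}: no disease passes the cutoff")
    prior = build_prior(symptom, diseases, net, weighted=prior_cfg.weighted)
    return propagate(Wn, prior, prop_cfg)


@dataclass
class PipelineResult:
    """Scores and per-symptom reports for a multi-symptom run."""

    scores: dict[str, ScoreVector]
    reports: dict[str, EvaluationReport]
    skipped: dict[str, str]  # symptom -> reason it could not be scored
    auc: float | None        # pooled over all evaluated symptoms


def run_pipeline(
    corpus: RecordCorpus,
    net: PhenoGenoNetwork,
    benchmark: dict[str, BenchmarkSet] | None = None,
    prior_cfg: PriorConfig = PriorConfig(),
    prop_cfg: PropagationConfig = PropagationConfig(),
    symptoms: list[str] | None = None,
    auc_mode: str = "pooled",
) -> PipelineResult:
    """Score every symptom of the corpus (or the given subset) and evaluate.

    Symptoms whose prior cannot be built (no disease above the cutoff, or no
    seed gene in the network) are recorded in ``skipped`` rather than
    aborting the batch.
    """
    table = build_similarity_table(corpus)
    cutoff = similarity_cutoff(table, prior_cfg)
    Wn = normalize_adjacency(net)
    if symptoms is None:
        symptoms = list(corpus.symptom_vocab)

    scores: dict[str, ScoreVector] = {}
    skipped: dict[str, str] = {}
    for s in symptoms:
        try:
            scores[s] = prioritize_symptom(
                s, table, net, prior_cfg, prop_cfg, Wn=Wn, cutoff=cutoff
            )
        except (UnknownSymptomError, NoSeedGenesError) as exc:
            skipped[s] = str(exc)

    reports: dict[str, EvaluationReport] = {}
    auc = None
    if benchmark:
        evaluable = [
            (scores[s], benchmark[s]) for s in scores if s in benchmark
        ]
        for F, bench in evaluable:
            reports[F.symptom] = evaluate_symptom(F, bench, prop_cfg)
        if evaluable:
            auc = pooled_auc(evaluable, mode=auc_mode)
    return PipelineResult(scores, reports, skipped, auc)
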