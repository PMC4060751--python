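"""Symptom/disease co-occurrence profiles and cosine similarity.

Symptoms and diseases are represented as vectors over a fixed symptom
vocabulary: coordinate ``j`` of an entity's profile counts the bibliographic
records in which the entity and symptom ``j`` appear together.  The
association between a symptom ``s`` and a disease ``d`` is the cosine of the
angle between their profiles,

    T(d, s) = d . s / (||d||_2 * ||s||_2),

which lies in [0, 1] because all counts are nonnegative.  Co-occurrence is
counted at whole-record granularity and is presence-based: a term appearing
twice in one record still counts once.  The self-coordinate of a symptom's
profile (co-occurrence of a symptom with itself) is its document frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "RecordCorpus",
    "CooccurrenceProfile",
    "SimilarityTable",
    "build_profiles",
    "cosine_similarity",
    "build_similarity_table",
    "read_corpus",
    "read_similarity_table",
    "write_similarity_table",
]


class UnknownTermError(ValueError):
    """A record mentions a term that is absent from its vocabulary."""


@dataclass(frozen=True)
class RecordCorpus:
    """A corpus of bibliographic records, each a set of symptom and disease terms.

    Parameters
    ----------
    records
        List of ``(record_id, symptoms, diseases)`` triples; the term sets may
        be empty.
    symptom_vocab
        Ordered symptom vocabulary of length ``n``; profiles are indexed by it.
    disease_vocab
        Ordered disease vocabulary.
    """

    records: tuple[tuple[str, frozenset[str], frozenset[str]], ...]
    symptom_vocab: tuple[str, ...]
    disease_vocab: tuple[str, ...]

    def __post_init__(self) -> None:
        for vocab, label in ((self.symptom_vocab, "symptom"), (self.disease_vocab, "disease")):
            if len(set(vocab)) != len(vocab):
                raise ValueError(f"duplicate terms in {label} vocabulary")
        sym = set(self.symptom_vocab)
        dis = set(self.disease_vocab)
        for rid, symptoms, diseases in self.records:
            for t in symptoms:
                if t not in sym:
                    raise UnknownTermError(
                        f"record {rid!r}: symptom term {t!r} not in symptom vocabulary"
                    )
            for t in diseases:
                if t not in dis:
                    raise UnknownTermError(
                        f"record {rid!r}: disease term {t!r} not in disease vocabulary"
                    )

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, Iterable[str], Iterable[str]]],
        symptom_vocab: Iterable[str] | None = None,
        disease_vocab: Iterable[str] | None = None,
    ) -> "RecordCorpus":
        """Build a corpus, inferring sorted vocabularies when not given."""
        recs = tuple(
            (rid, frozenset(sym), frozenset(dis)) for rid, sym, dis in records
        )
        if symptom_vocab is None:
            symptom_vocab = sorted(set().union(*(r[1] for r in recs)) if recs else set())
        if disease_vocab is None:
            disease_vocab = sorted(set().union(*(r[2] for r in recs)) if recs else set())
        return cls(recs, tuple(symptom_vocab), tuple(disease_vocab))

    @property
    def n_symptoms(self) -> int:
        return len(self.symptom_vocab)


@dataclass(frozen=True)
class CooccurrenceProfile:
    """Per-entity vector of record co-occurrence counts over the symptom vocabulary."""

    entity_id: str
    entity_kind: Literal["symptom", "disease"]
    counts: np.ndarray  # length-n vector of nonnegative ints, indexed by symptom_vocab

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        if (self.counts < 0).any():
            raise ValueError("co-occurrence counts must be nonnegative")


@dataclass
class SimilarityTable:
    """Sparse mapping ``(symptom, disease) -> cosine score`` in [0, 1].

    Only nonzero pairs are stored.  ``provenance`` records whether the table
    was computed from a corpus or loaded from a file.
    """

    entries: dict[tuple[str, str], float]
    provenance: Literal["computed", "loaded"] = "computed"

    def __post_init__(self) -> None:
        for (s, d), v in self.entries.items():
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"similarity for ({s!r}, {d!r}) outside [0,1]: {v}")

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, symptom: str, disease: str) -> float:
        return self.entries.get((symptom, disease), 0.0)

    def symptoms(self) -> list[str]:
        return sorted({s for s, _ in self.entries})

    def pairs_for_symptom(self, symptom: str) -> list[tuple[str, float]]:
        """All (disease, similarity) pairs for a symptom, unordered."""
        return [(d, v) for (s, d), v in self.entries.items() if s == symptom]

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, d, v) for (s, d), v in self.entries.items()]
        df = pd.DataFrame(rows, columns=["symptom", "disease", "similarity"])
        return df.sort_values(
            ["symptom", "similarity", "disease"], ascending=[True, False, True]
        ).reset_index(drop=True)


def _incidence(corpus: RecordCorpus) -> tuple[sparse.csr_matrix, sparse.csr_matrix]:
    """Binary record x term incidence matrices (symptoms, diseases)."""
    sym_idx = {t: j for j, t in enumerate(corpus.symptom_vocab)}
    dis_idx = {t: j for j, t in enumerate(corpus.disease_vocab)}
    n_rec = len(corpus.records)

    def build(index: Mapping[str, int], pick: int) -> sparse.csr_matrix:
        rows, cols = [], []
        for i, rec in enumerate(corpus.records):
            for t in rec[pick]:
                rows.append(i)
                cols.append(index[t])
        data = np.ones(len(rows), dtype=np.int64)
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(n_rec, len(index)), dtype=np.int64
        )

    return build(sym_idx, 1), build(dis_idx, 2)


def build_profiles(
    corpus: RecordCorpus,
) -> tuple[dict[str, CooccurrenceProfile], dict[str, CooccurrenceProfile]]:
    """Count record-level co-occurrence for every vocabulary entry.

    Returns ``(symptom_profiles, disease_profiles)``.  For disease ``d``,
    ``counts[j]`` is the number of records containing both ``d`` and symptom
    ``j``; for symptom ``i``, ``counts[j]`` counts records containing both
    symptoms ``i`` and ``j`` (so ``counts[i]`` is the document frequency of
    ``i``).
    """
    if not corpus.symptom_vocab or not corpus.disease_vocab:
        raise ValueError("corpus vocabularies must be nonempty")
    S, D = _incidence(corpus)
    sym_cooc = np.asarray((S.T @ S).todense())      # n x n
    dis_cooc = np.asarray((D.T @ S).todense())      # |diseases| x n
    symptom_profiles = {
        t: CooccurrenceProfile(t, "symptom", sym_cooc[j])
        for j, t in enumerate(corpus.symptom_vocab)
    }
    disease_profiles = {
        t: CooccurrenceProfile(t, "disease", dis_cooc[j])
        for j, t in enumerate(corpus.disease_vocab)
    }
    return symptom_profiles, disease_profiles


def cosine_similarity(a: CooccurrenceProfile, b: CooccurrenceProfile) -> float:
    """Cosine of the angle between two co-occurrence profiles.

    Returns 0.0 when either vector has zero norm (a rare term with no
    co-occurrences must not abort a batch run).
    """
    va, vb = a.counts, b.counts
    if va.shape != vb.shape:
        raise ValueError(
            f"profile length mismatch: {a.entity_id!r} has {va.shape[0]}, "
            f"{b.entity_id!r} has {vb.shape[0]}"
        )
    na = float(np.linalg.norm(va))
    nb = float(np.linalg.norm(vb))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(va @ vb) / (na * nb)


def build_similarity_table(corpus: RecordCorpus) -> SimilarityTable:
    """Cosine similarity for every (symptom, disease) pair; zero pairs omitted."""
    S, D = _incidence(corpus)
    sym_vecs = np.asarray((S.T @ S).todense(), dtype=float)
    dis_vecs = np.asarray((D.T @ S).todense(), dtype=float)
    sym_norm = np.linalg.norm(sym_vecs, axis=1)
    dis_norm = np.linalg.norm(dis_vecs, axis=1)
    dots = sym_vecs @ dis_vecs.T                    # n_sym x n_dis
    denom = np.outer(sym_norm, dis_norm)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where(denom > 0, dots / denom, 0.0)
    sims = np.clip(sims, 0.0, 1.0)
    entries: dict[tuple[str, str], float] = {}
    for i, s in enumerate(corpus.symptom_vocab):
        for j, d in enumerate(corpus.disease_vocab):
            if sims[i, j] > 0.0:
                entries[(s, d)] = float(sims[i, j])
    return SimilarityTable(entries, provenance="computed")


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_corpus(path: str | Path) -> RecordCorpus:
    """Read a corpus file: ``record_id TAB sym;sym TAB dis;dis`` per line.

    A header line is detected by the literal string ``record_id`` in the
    first field.  Empty term fields give empty sets.
    """
    records: list[tuple[str, frozenset[str], frozenset[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            rid, syms, dises = parts
            if lineno == 1 and rid.strip() == "record_id":
                continue
            split = lambda s: frozenset(t.strip() for t in s.split(";") if t.strip())
            records.append((rid.strip(), split(syms), split(dises)))
    return RecordCorpus.from_records(records)


def write_corpus(corpus: RecordCorpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("record_id\tsymptoms\tdiseases\n")
        for rid, syms, dises in corpus.records:
            fh.write(f"{rid}\t{';'.join(sorted(syms))}\t{';'.join(sorted(dises))}\n")


def read_similarity_table(path: str | Path) -> SimilarityTable:
    df = pd.read_csv(path, sep="\t", dtype={"symptom": str, "disease": str})
    entries = {
        (row.symptom, row.disease): float(row.similarity) for row in df.itertuples()
    }
    return SimilarityTable(entries, provenance="loaded")


def write_similarity_table(table: SimilarityTable, path: str | Path) -> None:
    """Write TSV sorted by (symptom, -similarity, disease)."""
    table.to_frame().to_csv(path, sep="\t", index=False)
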