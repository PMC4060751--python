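import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from symgene.cooccurrence import (
    CooccurrenceProfile,
    RecordCorpus,
    UnknownTermError,
    build_profiles,
    build_similarity_table,
    cosine_similarity,
    read_corpus,
    read_similarity_table,
    write_corpus,
    write_similarity_table,
)
from tests.conftest import random_corpus


def brute_force_counts(corpus):
    """Independent double loop over records and term pairs."""
    sym = {s: np.zeros(len(corpus.symptom_vocab), dtype=int) for s in corpus.symptom_vocab}
    dis = {d: np.zeros(len(corpus.symptom_vocab), dtype=int) for d in corpus.disease_vocab}
    for _, symptoms, diseases in corpus.records:
        for j, t in enumerate(corpus.symptom_vocab):
            if t not in symptoms:
                continue
            for s in symptoms:
                sym[s][j] += 1
            for d in diseases:
                dis[d][j] += 1
    return sym, dis


class TestBuildProfiles:
    def test_empty_corpus_gives_all_zero_profiles(self):
        corpus = RecordCorpus.from_records([], ["s1", "s2"], ["d1"])
        sym, dis = build_profiles(corpus)
        assert all(not p.counts.any() for p in sym.values())
        assert all(not p.counts.any() for p in dis.values())

    def test_single_record_counting(self):
        corpus = RecordCorpus.from_records(
            [("r1", {"s1", "s2"}, {"d1"})], ["s1", "s2"], ["d1"]
        )
        sym, dis = build_profiles(corpus)
        assert dis["d1"].counts.tolist() == [1, 1]
        assert sym["s1"].counts.tolist() == [1, 1]
        assert sym["s2"].counts.tolist() == [1, 1]

    def test_matches_brute_force_on_random_corpus(self, rng):
        corpus = random_corpus(rng, n_records=50)
        sym, dis = build_profiles(corpus)
        bf_sym, bf_dis = brute_force_counts(corpus)
        for s in corpus.symptom_vocab:
            assert sym[s].counts.tolist() == bf_sym[s].tolist()
        for d in corpus.disease_vocab:
            assert dis[d].counts.tolist() == bf_dis[d].tolist()

    def test_symptom_self_coordinate_is_document_frequency(self, rng):
        corpus = random_corpus(rng)
        sym, _ = build_profiles(corpus)
        for i, s in enumerate(corpus.symptom_vocab):
            df = sum(1 for _, syms, _ in corpus.records if s in syms)
            assert sym[s].counts[i] == df

    def test_unknown_term_rejected_with_name(self):
        with pytest.raises(UnknownTermError, match="mystery"):
            RecordCorpus.from_records(
                [("r1", {"mystery"}, set())], ["s1"], ["d1"]
            )


class TestCosineSimilarity:
    def test_identical_nonzero_vectors_give_one(self):
        p = CooccurrenceProfile("x", "symptom", [3, 1, 2])
        assert cosine_similarity(p, p) == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        a = CooccurrenceProfile("a", "symptom", [1, 0])
        b = CooccurrenceProfile("b", "disease", [0, 1])
        assert cosine_similarity(a, b) == 0.0

    def test_hand_arithmetic(self):
        # dot = 1*2 + 2*1 + 0*2 = 4, norms sqrt(5) and 3
        a = CooccurrenceProfile("a", "symptom", [1, 2, 0])
        b = CooccurrenceProfile("b", "disease", [2, 1, 2])
        assert cosine_similarity(a, b) == pytest.approx(4 / (math.sqrt(5) * 3))

    def test_zero_norm_gives_zero_not_error(self):
        a = CooccurrenceProfile("a", "symptom", [0, 0])
        b = CooccurrenceProfile("b", "disease", [1, 1])
        assert cosine_similarity(a, b) == 0.0

    def test_length_mismatch_rejected(self):
        a = CooccurrenceProfile("a", "symptom", [1])
        b = CooccurrenceProfile("b", "disease", [1, 1])
        with pytest.raises(ValueError, match="mismatch"):
            cosine_similarity(a, b)


class TestSimilarityTable:
    def test_table_equals_pairwise_cosine_of_profiles(self, rng):
        corpus = random_corpus(rng)
        table = build_similarity_table(corpus)
        sym, dis = build_profiles(corpus)
        for s in corpus.symptom_vocab:
            for d in corpus.disease_vocab:
                expected = cosine_similarity(sym[s], dis[d])
                assert table.get(s, d) == pytest.approx(expected, abs=1e-12)

    def test_zero_pairs_omitted(self):
        # d1 never co-occurs with any symptom record
        corpus = RecordCorpus.from_records(
            [("r1", {"s1"}, set()), ("r2", set(), {"d1"})], ["s1"], ["d1"]
        )
        table = build_similarity_table(corpus)
        assert ("s1", "d1") not in table.entries

    def test_matching_profiles_score_one(self):
        # d1 appears in exactly the records of s1, nothing else
        corpus = RecordCorpus.from_records(
            [("r1", {"s1"}, {"d1"}), ("r2", {"s1"}, {"d1"})], ["s1"], ["d1"]
        )
        table = build_similarity_table(corpus)
        assert table.get("s1", "d1") == pytest.approx(1.0)

    def test_planted_pair_is_argmax(self, rng):
        # a dedicated symptom-disease pair co-occurring alone in 30 records
        # has parallel profiles (similarity 1); background pairs do not
        corpus = random_corpus(rng, n_records=40)
        records = list(corpus.records) + [
            (f"p{i}", frozenset({"splant"}), frozenset({"dplant"})) for i in range(30)
        ]
        planted = RecordCorpus.from_records(
            records,
            list(corpus.symptom_vocab) + ["splant"],
            list(corpus.disease_vocab) + ["dplant"],
        )
        table = build_similarity_table(planted)
        assert table.get("splant", "dplant") == pytest.approx(1.0)
        best = max(table.entries, key=table.entries.get)
        assert best == ("splant", "dplant")

    def test_all_scores_in_unit_interval(self, rng):
        table = build_similarity_table(random_corpus(rng))
        assert all(0.0 <= v <= 1.0 for v in table.entries.values())


class TestInvariances:
    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_record_order_irrelevant(self, seed):
        rng = np.random.default_rng(seed)
        corpus = random_corpus(rng, n_records=15)
        perm = rng.permutation(len(corpus.records))
        shuffled = RecordCorpus(
            tuple(corpus.records[i] for i in perm),
            corpus.symptom_vocab,
            corpus.disease_vocab,
        )
        t1 = build_similarity_table(corpus)
        t2 = build_similarity_table(shuffled)
        assert t1.entries == t2.entries

    def test_duplicating_records_preserves_cosine(self, rng):
        corpus = random_corpus(rng, n_records=20)
        doubled = RecordCorpus.from_records(
            [(f"{rid}-{k}", syms, dis) for rid, syms, dis in corpus.records for k in (0, 1)],
            corpus.symptom_vocab,
            corpus.disease_vocab,
        )
        t1 = build_similarity_table(corpus)
        t2 = build_similarity_table(doubled)
        assert set(t1.entries) == set(t2.entries)
        for key, v in t1.entries.items():
            assert t2.entries[key] == pytest.approx(v, abs=1e-12)


class TestIO:
    def test_corpus_roundtrip(self, rng, tmp_path):
        corpus = random_corpus(rng, n_records=10)
        path = tmp_path / "corpus.tsv"
        write_corpus(corpus, path)
        back = read_corpus(path)
        assert set(back.records) == set(corpus.records)

    def test_similarity_table_roundtrip_and_sort(self, rng, tmp_path):
        table = build_similarity_table(random_corpus(rng))
        path = tmp_path / "sim.tsv"
        write_similarity_table(table, path)
        back = read_similarity_table(path)
        assert back.provenance == "loaded"
        for key, v in table.entries.items():
            assert back.entries[key] == pytest.approx(v, abs=1e-9)
        # sorted by (symptom, -similarity, disease)
        df = table.to_frame()
        for _, grp in df.groupby("symptom"):
            assert (grp.similarity.diff().dropna() <= 1e-15).all()

    def test_malformed_corpus_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("record_id\tsymptoms\tdiseases\nr1\ts1\n")
        with pytest.raises(ValueError, match="line 2"):
            read_corpus(path)
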