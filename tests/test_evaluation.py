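import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from symgene.evaluation import (
    BenchmarkSet,
    evaluate_symptom,
    fold_enrichment,
    monte_carlo_expected_overlap,
    pooled_auc,
    rank_auc,
    read_benchmark,
    recall_in_list,
)
from symgene.propagation import PropagationConfig, ScoreVector


def score_vector(genes, scores, symptom="s"):
    return ScoreVector(symptom, np.asarray(scores, dtype=float), tuple(genes), 1, True)


def brute_force_auc(pos, neg):
    """Oracle: fraction of correctly ordered (positive, negative) pairs, ties 1/2."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRecall:
    def test_superset_gives_100(self):
        bench = BenchmarkSet("s", frozenset({"a", "b"}))
        assert recall_in_list(["a", "b", "c"], bench) == 100.0

    def test_disjoint_gives_0(self):
        bench = BenchmarkSet("s", frozenset({"a"}))
        assert recall_in_list(["x", "y"], bench) == 0.0

    def test_accepts_ranked_tuples(self):
        bench = BenchmarkSet("s", frozenset({"a", "b", "c", "d"}))
        assert recall_in_list([("a", 0.5, 1), ("x", 0.4, 2)], bench) == 25.0

    def test_monotone_in_list_length(self, rng):
        genes = [f"g{i}" for i in range(50)]
        bench = BenchmarkSet("s", frozenset(rng.choice(genes, 10, replace=False)))
        prev = -1.0
        for k in range(1, 51, 7):
            r = recall_in_list(genes[:k], bench)
            assert r >= prev
            prev = r

    def test_empty_benchmark_rejected(self):
        with pytest.raises(ValueError):
            BenchmarkSet("s", frozenset())


class TestRankAuc:
    def test_perfect_separation_gives_one(self):
        F = score_vector(["a", "b", "c", "d"], [0.9, 0.8, 0.2, 0.1])
        assert rank_auc(F, BenchmarkSet("s", frozenset({"a", "b"}))) == 1.0

    def test_interleaved_example(self):
        # positives at 0.9 and 0.2: 3 of 4 (pos, neg) pairs correctly ordered
        F = score_vector(["a", "b", "c", "d"], [0.9, 0.8, 0.2, 0.1])
        assert rank_auc(F, BenchmarkSet("s", frozenset({"a", "c"}))) == 0.75

    def test_disjoint_benchmark_rejected(self):
        F = score_vector(["a", "b"], [0.5, 0.1])
        with pytest.raises(ValueError, match="disjoint"):
            rank_auc(F, BenchmarkSet("s", frozenset({"zz"})))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        genes = [f"g{i:03d}" for i in range(n)]
        # quantized scores force ties across classes
        scores = np.round(rng.random(n), 2)
        n_pos = int(rng.integers(1, n))
        positives = set(rng.choice(genes, n_pos, replace=False))
        F = score_vector(genes, scores)
        bench = BenchmarkSet("s", frozenset(positives))
        labels = np.array([g in positives for g in genes])
        expected = brute_force_auc(scores[labels], scores[~labels])
        got = rank_auc(F, bench)
        assert got == pytest.approx(expected, abs=1e-12)
        # independent library cross-check
        assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_identical_score_distributions_near_half(self):
        rng = np.random.default_rng(7)
        n = 5000
        genes = [f"g{i}" for i in range(n)]
        scores = rng.random(n)
        positives = set(rng.choice(genes, 500, replace=False))
        F = score_vector(genes, scores)
        auc = rank_auc(F, BenchmarkSet("s", frozenset(positives)))
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_pooled_vs_mean_modes(self):
        F1 = score_vector(["a", "b"], [0.9, 0.1], "s1")
        F2 = score_vector(["a", "b"], [0.2, 0.8], "s2")
        pairs = [
            (F1, BenchmarkSet("s1", frozenset({"a"}))),
            (F2, BenchmarkSet("s2", frozenset({"b"}))),
        ]
        assert pooled_auc(pairs, mode="mean") == 1.0
        # pooled mixes the two score scales: positives 0.9, 0.8 vs negatives 0.1, 0.2
        assert pooled_auc(pairs, mode="pooled") == 1.0


class TestFoldEnrichment:
    def test_certainty_when_whole_universe_selected(self):
        e = fold_enrichment(27, 100, 27, 100)
        assert e.expected == pytest.approx(27.0)

    def test_zero_observed_gives_zero_fold(self):
        assert fold_enrichment(0, 50, 10, 1000).fold == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(1, 10, 5, 0)
        with pytest.raises(ValueError):
            fold_enrichment(11, 10, 20, 100)
        with pytest.raises(ValueError):
            fold_enrichment(1, 200, 5, 100)

    def test_expected_matches_monte_carlo(self):
        rng = np.random.default_rng(11)
        e = fold_enrichment(10, 251, 27, 14221)
        mean, se = monte_carlo_expected_overlap(251, 27, 14221, n_draws=100_000, rng=rng)
        assert abs(mean - e.expected) < 3 * se


class TestEvaluateSymptom:
    def test_hand_built_toy(self):
        # 6 genes; cutoff 0.01 keeps the top 3; benchmark {a, e} -> 1 hit
        F = score_vector(list("abcdef"), [0.5, 0.3, 0.02, 0.009, 0.001, 0.0])
        bench = BenchmarkSet("s", frozenset({"a", "e"}))
        rep = evaluate_symptom(F, bench, PropagationConfig(score_cutoff=0.01))
        assert rep.enrichment.k == 3
        assert rep.enrichment.observed == 1
        assert rep.recall_at_list == pytest.approx(50.0)
        assert rep.enrichment.per_gene_prob == pytest.approx(2 / 6)
        assert rep.enrichment.expected == pytest.approx(1.0)
        assert rep.enrichment.fold == pytest.approx(1.0)
        # positives a (0.5) and e (0.001): a beats all 4 negatives, e beats 1
        assert rep.auc == pytest.approx(brute_force_auc([0.5, 0.001], [0.3, 0.02, 0.009, 0.0]))

    def test_empty_overlap(self):
        F = score_vector(["a", "b", "c"], [0.5, 0.02, 0.001])
        bench = BenchmarkSet("s", frozenset({"c"}))
        rep = evaluate_symptom(F, bench, PropagationConfig(score_cutoff=0.01))
        assert rep.recall_at_list == 0.0
        assert rep.enrichment.fold == 0.0
        assert rep.auc is not None

    def test_unscored_benchmark_genes_counted(self):
        F = score_vector(["a", "b"], [0.5, 0.1])
        bench = BenchmarkSet("s", frozenset({"a", "offnet"}))
        rep = evaluate_symptom(F, bench)
        assert rep.n_unscored == 1

    def test_report_rounding(self):
        F = score_vector(["a", "b", "c"], [0.5, 0.2, 0.001])
        rep = evaluate_symptom(F, BenchmarkSet("s", frozenset({"a"})))
        d = rep.to_dict()
        assert d["enrichment"]["per_gene_prob"] == round(1 / 3, 7)


def test_read_benchmark(tmp_path):
    path = tmp_path / "bench.tsv"
    path.write_text("s1\tBRCA1\ns1\tbrca1\ns2\tTP53\n")
    got = read_benchmark(path)
    assert got["s1"].genes == frozenset({"BRCA1"})
    assert got["s2"].genes == frozenset({"TP53"})
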