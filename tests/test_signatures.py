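"""Importance ranking, direction split, overlap test, clustering purity."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from atrasens import (
    ExpressionMatrix,
    GeneSet,
    ValidationError,
    cluster_and_separate,
    overlap_count,
    rank_genes_by_importance,
    split_by_direction,
)
from atrasens.data_model import SampleAnnotation


def _perfect_predictor_matrix(n_samples=30, n_noise=30, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"s{i:02d}" for i in range(n_samples)]
    scores = pd.Series(rng.uniform(0, 1, n_samples), index=samples)
    rows = {"sig": scores.to_numpy()}
    for j in range(n_noise):
        rows[f"noise{j:02d}"] = rng.normal(size=n_samples)
    expr = ExpressionMatrix(pd.DataFrame(rows, index=samples).T)
    return expr, scores


class TestRanking:
    def test_perfect_predictor_ranks_first(self):
        expr, scores = _perfect_predictor_matrix()
        ranked = rank_genes_by_importance(expr, scores, n_trees=200, seed=0)
        assert ranked.entries.iloc[0]["gene"] == "sig"
        assert ranked.model_meta["oob_r2"] > 0.3
        assert list(ranked.entries["rank"]) == list(range(1, 32))

    def test_seed_determinism_and_sample_order_invariance(self):
        expr, scores = _perfect_predictor_matrix(seed=1)
        r1 = rank_genes_by_importance(expr, scores, n_trees=100, seed=5)
        r2 = rank_genes_by_importance(expr, scores, n_trees=100, seed=5)
        pd.testing.assert_frame_equal(r1.entries, r2.entries)
        shuffled = ExpressionMatrix(
            expr.values[expr.values.columns[::-1]])
        r3 = rank_genes_by_importance(shuffled, scores, n_trees=100, seed=5)
        pd.testing.assert_frame_equal(r1.entries, r3.entries)

    def test_zero_variance_genes_dropped_with_warning(self, caplog):
        expr, scores = _perfect_predictor_matrix(seed=2)
        values = expr.values.copy()
        values.loc["flat"] = 1.0
        with caplog.at_level("WARNING", logger="atrasens"):
            ranked = rank_genes_by_importance(
                ExpressionMatrix(values), scores, n_trees=50, seed=0)
        assert "flat" not in set(ranked.entries["gene"])
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_too_few_samples_rejected(self):
        expr, scores = _perfect_predictor_matrix(n_samples=8)
        with pytest.raises(ValidationError):
            rank_genes_by_importance(expr, scores, n_trees=10, seed=0)

    def test_permuted_scores_destroy_signal(self, small_cohort):
        rng = np.random.default_rng(0)
        permuted = pd.Series(
            rng.permutation(small_cohort.scores.to_numpy()),
            index=small_cohort.scores.index)
        ranked = rank_genes_by_importance(small_cohort.expr, permuted,
                                          n_trees=300, seed=1)
        assert ranked.model_meta["oob_r2"] <= 0.1


class TestDirectionSplit:
    def test_planted_positive_genes_go_up(self, small_cohort):
        ranked = rank_genes_by_importance(small_cohort.expr,
                                          small_cohort.scores,
                                          n_trees=300, seed=2)
        up, down = split_by_direction(ranked, small_cohort.expr,
                                      small_cohort.scores, top_k=20)
        planted = set(small_cohort.informative_genes)
        assert planted & set(ranked.top(20)) <= set(up.genes)
        assert up.direction == "up" and down.direction == "down"

    def test_negated_gene_goes_down(self, small_cohort):
        values = small_cohort.expr.values.copy()
        g = small_cohort.informative_genes[0]
        values.loc[g] = -values.loc[g]
        expr = ExpressionMatrix(values)
        ranked = rank_genes_by_importance(expr, small_cohort.scores,
                                          n_trees=300, seed=2)
        up, down = split_by_direction(ranked, expr, small_cohort.scores,
                                      top_k=20)
        if g in set(ranked.top(20)):
            assert g in set(down.genes)

    def test_full_split_partitions_list(self, small_cohort):
        ranked = rank_genes_by_importance(small_cohort.expr,
                                          small_cohort.scores,
                                          n_trees=100, seed=3)
        k = len(ranked.entries)
        up, down = split_by_direction(ranked, small_cohort.expr,
                                      small_cohort.scores, top_k=k)
        assert sorted(up.genes + down.genes) == sorted(ranked.genes)
        assert not set(up.genes) & set(down.genes)


def hypergeom_tail_oracle(count, universe, n_a, n_b):
    """P(overlap >= count) by exhaustive summation of the pmf."""
    def comb(n, k):
        return math.comb(n, k)
    total = comb(universe, n_b)
    p = 0.0
    for k in range(count, min(n_a, n_b) + 1):
        p += comb(n_a, k) * comb(universe - n_a, n_b - k) / total
    return p


class TestOverlap:
    def test_identical_sets_extreme(self):
        genes = [f"g{i}" for i in range(100)]
        res = overlap_count(GeneSet("a", genes), GeneSet("b", list(genes)),
                            universe_size=15543)
        assert res["count"] == 100
        assert res["hypergeometric_p"] < 1e-100

    def test_disjoint_sets(self):
        res = overlap_count(GeneSet("a", ["x", "y"]), GeneSet("b", ["u", "v"]),
                            universe_size=100)
        assert res["count"] == 0
        assert res["hypergeometric_p"] == pytest.approx(1.0)

    def test_agrees_with_enumeration_oracle_small_universe(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(40)]
        for _ in range(25):
            a = list(rng.choice(universe, size=8, replace=False))
            b = list(rng.choice(universe, size=12, replace=False))
            res = overlap_count(GeneSet("a", a), GeneSet("b", b), 40)
            expected = hypergeom_tail_oracle(res["count"], 40, 8, 12)
            assert res["hypergeometric_p"] == pytest.approx(expected,
                                                            rel=1e-9)

    def test_random_sets_mean_overlap_matches_expectation(self):
        rng = np.random.default_rng(5)
        universe = np.arange(10_000)
        overlaps = []
        for _ in range(300):
            a = set(rng.choice(universe, 100, replace=False))
            b = set(rng.choice(universe, 100, replace=False))
            overlaps.append(len(a & b))
        assert np.mean(overlaps) == pytest.approx(1.0, abs=0.3)

    def test_inconsistent_universe_rejected(self):
        with pytest.raises(ValidationError):
            overlap_count(GeneSet("a", ["x", "y"]), GeneSet("b", ["z"]), 2)


def _block_cohort(noise=0.0, seed=0, n_per=5, duplicate=False):
    """Two expression blocks aligned with T1/T3 membership."""
    rng = np.random.default_rng(seed)
    samples = [f"t1_{i}" for i in range(n_per)] + \
              [f"t3_{i}" for i in range(n_per)]
    base = np.zeros((20, 2 * n_per))
    base[:10, :n_per] = 2.0   # block genes high in T1
    base[10:, n_per:] = 2.0   # other block high in T3
    base += rng.normal(0, max(noise, 1e-6), base.shape)
    if duplicate:
        base = np.hstack([base, base])
        samples = samples + [s + "_dup" for s in samples]
    expr = ExpressionMatrix(pd.DataFrame(
        base, index=[f"g{i}" for i in range(20)], columns=samples))
    annot = SampleAnnotation(pd.DataFrame(
        {"tertile": ["T1" if s.startswith("t1") else "T3" for s in samples]},
        index=samples))
    return expr, annot


class TestClustering:
    def test_block_structure_perfect_purity(self):
        expr, annot = _block_cohort()
        rep = cluster_and_separate(expr, annot)
        assert rep.purity == 1.0
        assert rep.linkage == "average" and rep.distance == "1-pearson"

    def test_shuffled_labels_near_chance(self):
        expr, annot = _block_cohort(noise=0.3, seed=1, n_per=10)
        rng = np.random.default_rng(2)
        purities = []
        for _ in range(30):
            shuffled = annot.table.copy()
            shuffled["tertile"] = rng.permutation(
                shuffled["tertile"].to_numpy())
            purities.append(cluster_and_separate(
                expr, SampleAnnotation(shuffled)).purity)
        # permutation distribution centers near 0.5 (plus the max() lift)
        assert np.mean(purities) < 0.75

    def test_duplicating_samples_keeps_purity(self):
        expr, annot = _block_cohort(noise=0.2, seed=3)
        base = cluster_and_separate(expr, annot).purity
        expr2, annot2 = _block_cohort(noise=0.2, seed=3, duplicate=True)
        assert cluster_and_separate(expr2, annot2).purity == \
            pytest.approx(base, abs=1e-12)

    def test_too_few_labeled_samples_rejected(self):
        expr, annot = _block_cohort()
        annot.table.loc[annot.table["tertile"] == "T3", "tertile"] = "unset"
        annot.table.iloc[0, annot.table.columns.get_loc("tertile")] = "T3"
        with pytest.raises(ValidationError):
            cluster_and_separate(expr, annot)
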