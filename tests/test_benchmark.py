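"""Fisher enrichment, AUROC/AUPR, permutation nulls and overlap arithmetic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import organgrn as og
from organgrn.benchmark import (
    aupr_from_scores,
    auroc_from_scores,
    benjamini_hochberg,
)
from organgrn.inference import RankedEdgeList, sort_edges


def _hypergeom_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by direct summation over all tables with the
    observed margins, summing tables at most as probable as the observed."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def table_prob(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))

    p_obs = table_prob(a)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = table_prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestBuildGoldStandard:
    def test_strict_threshold(self):
        assignments = {
            "exp1": {"tfA": {f"g{i}" for i in range(10)},
                     "tfB": {f"g{i}" for i in range(11)}},
        }
        gold = og.build_gold_standard(assignments, min_targets=10)
        assert set(gold.targets) == {"tfB"}  # strictly more than 10

    def test_union_across_experiments(self):
        assignments = {
            "exp1": {"tf": {"g1", "g2"}},
            "exp2": {"tf": {"g2", "g3"}},
        }
        gold = og.build_gold_standard(assignments, min_targets=2)
        assert gold.targets == {"tf": {"g1", "g2", "g3"}}

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            og.build_gold_standard({})


class TestFisherEnrichment:
    def test_hand_computed_table(self):
        # a=10 b=10 c=10 d=70: OR = (10*70)/(10*10) = 7
        universe = set(range(100))
        pred = set(range(20))
        gold = set(range(10)) | set(range(20, 30))
        entry = og.fisher_enrichment(pred, gold, universe)
        assert (entry["a"], entry["b"], entry["c"], entry["d"]) == (10, 10, 10, 70)
        assert entry["odds_ratio"] == pytest.approx(7.0)
        assert entry["log2_odds_ratio"] == pytest.approx(math.log2(7), abs=1e-9)
        assert entry["p_value"] == pytest.approx(
            _hypergeom_two_sided_oracle(10, 10, 10, 70), rel=1e-9
        )

    def test_independence_table(self):
        universe = set(range(80))
        pred = set(range(40))
        gold = set(range(20)) | set(range(40, 60))
        entry = og.fisher_enrichment(pred, gold, universe)
        assert entry["odds_ratio"] == pytest.approx(1.0)
        assert entry["log2_odds_ratio"] == pytest.approx(0.0)

    def test_zero_cell_correction_finite(self):
        universe = set(range(50))
        pred = set(range(10))
        gold = set(range(20))  # pred subset of gold: b = 0
        entry = og.fisher_enrichment(pred, gold, universe)
        assert np.isfinite(entry["odds_ratio"])
        assert entry["odds_ratio"] > 1

    def test_p_matches_oracle_on_small_margins(self, rng):
        universe = set(range(40))
        for _ in range(20):
            pred = set(rng.choice(40, size=rng.integers(1, 20), replace=False))
            gold = set(rng.choice(40, size=rng.integers(1, 20), replace=False))
            entry = og.fisher_enrichment(pred, gold, universe)
            oracle = _hypergeom_two_sided_oracle(
                entry["a"], entry["b"], entry["c"], entry["d"]
            )
            assert entry["p_value"] == pytest.approx(oracle, rel=1e-6)

    def test_universe_containment_enforced(self):
        with pytest.raises(ValueError):
            og.fisher_enrichment({1, 99}, {1}, set(range(10)))

    def test_batch_bh_adjustment(self):
        entries = [
            og.fisher_enrichment(set(range(k)), set(range(5)), set(range(50)),
                                 name=f"c{k}")
            for k in (5, 10, 20)
        ]
        table = og.fisher_batch(entries)
        raw = table["p_value"].to_numpy()
        expected = benjamini_hochberg(raw)
        np.testing.assert_allclose(table["p_adjusted"], expected)
        assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()


class TestRocPr:
    def _ranked(self, weights, pairs):
        edges = pd.DataFrame(
            [(r, t, w) for (r, t), w in zip(pairs, weights)],
            columns=["regulator", "target", "weight"],
        )
        return RankedEdgeList(sort_edges(edges))

    def test_perfect_separation(self):
        pairs = [("tf", f"g{i}") for i in range(6)]
        ranked = self._ranked([6, 5, 4, 3, 2, 1], pairs)
        gold = og.GoldStandard({"tf": {"g0", "g1"}})
        auroc, aupr = og.roc_pr(ranked, gold)
        assert auroc == 1.0 and aupr == 1.0

    def test_worst_case(self):
        pairs = [("tf", f"g{i}") for i in range(6)]
        ranked = self._ranked([1, 2, 3, 4, 5, 6], pairs)
        gold = og.GoldStandard({"tf": {"g0", "g1"}})
        auroc, _ = og.roc_pr(ranked, gold)
        assert auroc == 0.0

    def test_auroc_matches_concordant_pair_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 100))
            scores = rng.normal(size=n)
            labels = rng.random(n) < 0.3
            if labels.all() or not labels.any():
                continue
            # brute-force concordant-pair fraction with half-credit ties
            pos = scores[labels]
            neg = scores[~labels]
            wins = sum((p > q) + 0.5 * (p == q)
                       for p, q in itertools.product(pos, neg))
            assert auroc_from_scores(scores, labels) == pytest.approx(
                wins / (len(pos) * len(neg))
            )

    def test_aupr_equals_average_precision_without_ties(self, rng):
        from sklearn.metrics import average_precision_score

        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.25
        assert aupr_from_scores(scores, labels) == pytest.approx(
            average_precision_score(labels, scores)
        )

    def test_shared_regulator_filtering(self):
        pairs = [("tfA", "g1"), ("tfA", "g2"), ("tfZ", "g1")]
        ranked = self._ranked([3, 2, 1], pairs)
        gold = og.GoldStandard({"tfA": {"g1"}})  # tfZ edges must be ignored
        auroc, _ = og.roc_pr(ranked, gold)
        assert auroc == 1.0

    def test_degenerate_labels_error(self):
        pairs = [("tf", "g1"), ("tf", "g2")]
        ranked = self._ranked([2, 1], pairs)
        with pytest.raises(ValueError, match="positive|negative"):
            og.roc_pr(ranked, og.GoldStandard({"tf": {"g1", "g2"}}))


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(3)
    pairs = [("tf", f"g{i}") for i in range(500)]
    weights = rng.random(500)
    edges = pd.DataFrame(
        [(r, t, w) for (r, t), w in zip(pairs, weights)],
        columns=["regulator", "target", "weight"],
    )
    gold = og.GoldStandard({"tf": {f"g{i}" for i in range(0, 500, 5)}})
    return RankedEdgeList(sort_edges(edges)), gold


class TestPermutationTest:

    def test_null_mean_at_chance(self, toy):
        ranked, gold = toy
        out = og.permutation_test(ranked, gold, n_perm=500, seed=1)
        assert 0.48 <= out["null_auroc_mean"] <= 0.52

    def test_separating_ranking_significant(self):
        pairs = [("tf", f"g{i}") for i in range(500)]
        gold_targets = {f"g{i}" for i in range(100)}
        weights = [2.0 if f"g{i}" in gold_targets else 1.0 for i in range(500)]
        edges = pd.DataFrame(
            [(r, t, w) for (r, t), w in zip(pairs, weights)],
            columns=["regulator", "target", "weight"],
        )
        ranked = RankedEdgeList(sort_edges(edges))
        out = og.permutation_test(
            ranked, og.GoldStandard({"tf": gold_targets}), n_perm=200, seed=2
        )
        assert out["auroc_significant"] and out["aupr_significant"]

    def test_deterministic_under_seed(self, toy):
        ranked, gold = toy
        a = og.permutation_test(ranked, gold, n_perm=100, seed=9)
        b = og.permutation_test(ranked, gold, n_perm=100, seed=9)
        assert a == b

    def test_random_ranking_auroc_band_over_seeds(self, toy):
        ranked, gold = toy
        rng = np.random.default_rng(0)
        weights, labels = (
            ranked.edges["weight"].to_numpy(),
            np.array([t in gold.targets["tf"] for t in ranked.edges["target"]]),
        )
        inside = sum(
            0.4 <= auroc_from_scores(rng.permutation(weights), labels) <= 0.6
            for _ in range(100)
        )
        assert inside >= 95


class TestOverlapPercentage:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (369, 607, 61),   # 60.79 rounds up
            (740, 827, 89),
            (75, 168, 45),
            (319, 410, 78),
            (39, 49, 80),
            (16, 22, 73),
            (0, 50, 0),
            (1, 200, 1),      # 0.5 rounds half-away-from-zero
        ],
    )
    def test_rounding(self, k, n, expected):
        assert og.overlap_percentage(k, n) == expected

    def test_digits(self):
        assert og.overlap_percentage(26910, 37467, 2) == 71.82
        assert og.overlap_percentage(19361, 26910, 2) == 71.95
        assert og.overlap_percentage(1014, 1612, 1) == 62.9

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            og.overlap_percentage(1, 0)
        with pytest.raises(ValueError):
            og.overlap_percentage(5, 3)


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(40)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(benjamini_hochberg(p), expected)
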