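import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_dependency, make_expression
from sliminer.core_data import FeatureMatrix, GeneId, Modality
from sliminer.sli_scoring import (
    CutoffConfig,
    DegenerateInputError,
    PairScore,
    build_hit_list,
    classify_dependency,
    classify_expression,
    directional_rank_key,
    known_partner_rank,
    pearson_r_p,
    score_pairs,
)


def oracle_pearson(x, y):
    """Independent product-moment oracle: explicit sums, no library call."""
    x, y = list(x), list(y)
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


class TestPearson:
    def test_perfect_collinearity(self):
        res = pearson_r_p([1, 2, 3], [2, 4, 6])
        assert res.r == pytest.approx(1.0)
        assert 0 < res.p <= 1

    def test_hand_oracle_value(self):
        # product-moment by hand: r = 3 / sqrt(5*5) = 0.6
        res = pearson_r_p([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6, abs=1e-12)
        assert res.r == pytest.approx(oracle_pearson([1, 2, 3, 4], [2, 1, 4, 3]), abs=1e-12)

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_r_p([1, 1, 1], [1, 2, 3])

    def test_too_few_pairs(self):
        with pytest.raises(DegenerateInputError):
            pearson_r_p([1, 2], [3, 4])

    def test_missing_entries_removed_pairwise(self):
        res = pearson_r_p([1, 2, 3, 4, np.nan], [2, 1, 4, 3, 100])
        assert res.n == 4
        assert res.r == pytest.approx(0.6)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        assert pearson_r_p(x, y).r == pearson_r_p(y, x).r


class TestScorePairs:
    def test_single_pair_self_correlation(self):
        v = np.arange(30, dtype=float)
        a = make_expression([v], genes=["A"], samples=[f"s{i}" for i in range(30)])
        t = make_dependency([v.copy()], genes=["T"], samples=[f"s{i}" for i in range(30)])
        scan = score_pairs(a, t, min_overlap=10)
        assert len(scan.scores) == 1
        s = scan.scores[0]
        assert s.r == pytest.approx(1.0)
        assert s.p_bonferroni == pytest.approx(s.p)  # one test: no inflation

    def test_vectorized_matches_per_pair_oracle(self):
        rng = np.random.default_rng(7)
        n_a, n_t, n_s = 50, 40, 60
        X = rng.normal(size=(n_a, n_s))
        Y = rng.normal(size=(n_t, n_s))
        # sprinkle missing values to exercise pairwise-complete handling
        X[rng.random(X.shape) < 0.05] = np.nan
        Y[rng.random(Y.shape) < 0.05] = np.nan
        a = make_expression(X, genes=[f"A{i}" for i in range(n_a)])
        t = make_dependency(Y, genes=[f"T{j}" for j in range(n_t)])
        scan = score_pairs(a, t, min_overlap=30)
        assert scan.n_tests == len(scan.scores)
        for s in scan.scores:
            x = a.values_for(s.anchor.symbol)
            y = t.values_for(s.target.symbol)
            mask = ~(np.isnan(x) | np.isnan(y))
            assert abs(s.r - oracle_pearson(x[mask], y[mask])) < 1e-10
            assert s.n == int(mask.sum())

    def test_low_overlap_pair_skipped_and_counted(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2, 40))
        X[0, 15:] = np.nan  # anchor A0 only observed in 15 samples
        Y = rng.normal(size=(1, 40))
        a = make_expression(X, genes=["A0", "A1"])
        t = make_dependency(Y, genes=["T0"])
        scan = score_pairs(a, t, min_overlap=30)
        assert {s.anchor.symbol for s in scan.scores} == {"A1"}
        assert scan.n_skipped_overlap == 1

    def test_bonferroni_monotone_in_test_count(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 50))
        Y = rng.normal(size=(10, 50))
        a = make_expression(X, genes=[f"A{i}" for i in range(10)])
        t = make_dependency(Y, genes=[f"T{j}" for j in range(10)])
        small = score_pairs(a, t, targets=[f"T{j}" for j in range(5)], min_overlap=10)
        big = score_pairs(a, t, min_overlap=10)
        big_lookup = {
            (s.anchor.symbol, s.target.symbol): s.p_bonferroni for s in big.scores
        }
        for s in small.scores:
            assert big_lookup[(s.anchor.symbol, s.target.symbol)] >= s.p_bonferroni - 1e-15


def _score(anchor, target, r, modality=Modality.rna, n=100):
    return PairScore(
        anchor=GeneId(anchor), target=GeneId(target), modality=modality,
        r=r, r_directional=r if modality in (Modality.rna, Modality.protein) else -r,
        p=0.01, p_bonferroni=0.05, n=n,
    )


class TestDirectionalRanking:
    def test_rna_orders_by_descending_r(self):
        hi = _score("A", "T1", 0.6)
        lo = _score("B", "T2", 0.3)
        assert directional_rank_key(hi) < directional_rank_key(lo)

    def test_methylation_ranking_is_reversed(self):
        strong = _score("A", "T1", -0.6, Modality.methylation)
        weak = _score("B", "T2", -0.3, Modality.methylation)
        assert directional_rank_key(strong) < directional_rank_key(weak)

    def test_mixed_modality_compares_on_directional_r(self):
        rna = _score("A", "T1", 0.5, Modality.rna)
        meth = _score("B", "T2", -0.7, Modality.methylation)
        assert directional_rank_key(meth) < directional_rank_key(rna)


class TestKnownPartnerRank:
    def test_rank_three_of_hundred_is_significant(self):
        scores = [_score("A", f"T{i}", 1.0 - i * 0.01) for i in range(100)]
        rank, n, sig = known_partner_rank("A", "T2", scores, top_fraction=0.05)
        assert (rank, n, sig) == (3, 100, True)

    def test_rank_six_of_hundred_is_not(self):
        scores = [_score("A", f"T{i}", 1.0 - i * 0.01) for i in range(100)]
        rank, n, sig = known_partner_rank("A", "T5", scores, top_fraction=0.05)
        assert (rank, sig) == (6, False)

    def test_cut_at_rank_900_of_18000(self):
        assert math.ceil(0.05 * 18_000) == 900  # documented cut arithmetic
        scores = [_score("A", f"T{i}", 1.0 - i * 1e-5) for i in range(1000)]
        rank, n, sig = known_partner_rank("A", "T899", scores, top_fraction=0.9)
        assert rank == 900

    def test_unscored_partner_reported_missing(self):
        scores = [_score("A", "T1", 0.4)]
        rank, n, sig = known_partner_rank("A", "ABSENT", scores)
        assert rank is None and not sig


class TestHitList:
    def test_duplicate_target_keeps_better_anchor(self):
        s1 = _score("A1", "T", 0.8)
        s2 = _score("A2", "T", 0.5)
        hits = build_hit_list([s1, s2])
        assert [(h.anchor.symbol, h.target.symbol) for h in hits] == [("A1", "T")]

    def test_distinct_targets_unchanged(self):
        scores = [_score(f"A{i}", f"T{i}", 0.9 - 0.1 * i) for i in range(4)]
        hits = build_hit_list(scores)
        assert len(hits) == 4
        assert [h.hit_rank for h in hits] == [1, 2, 3, 4]

    def test_tie_keeps_lexicographically_smaller_anchor(self):
        s1 = _score("B", "T", 0.5)
        s2 = _score("A", "T", 0.5)
        hits = build_hit_list([s1, s2])
        assert hits[0].anchor.symbol == "A"

    def test_empty_input_empty_output(self):
        assert build_hit_list([]) == []

    def test_planted_pairs_recovered_and_decoys_removed(self, default_cohort, default_scan):
        hits = build_hit_list(default_scan.scores)
        top10 = {(h.anchor.symbol, h.target.symbol) for h in hits[:10]}
        for pair in default_cohort.truth:
            assert (pair.anchor, pair.target) in top10
        assert not any(h.anchor.symbol.startswith("DECOY") for h in hits)


class TestClassifiers:
    @pytest.mark.parametrize(
        "score,expected", [(-0.6, True), (-0.5, False), (0.0, False)]
    )
    def test_lethality_is_strictly_below_cutoff(self, score, expected):
        assert classify_dependency(score) is expected

    def test_missing_score_unclassified(self):
        assert classify_dependency(float("nan")) is None

    @pytest.mark.parametrize(
        "gene,value,mode,expected",
        [
            ("CDS1", 1.4, "low", True),
            ("CDS1", 1.5, "low", False),
            ("CDH1", 4.5, "high", True),  # boundary counts as high (>=)
            ("ZEB1", 1.9, "high", False),
            ("VIM", 6.2, "high", True),
        ],
    )
    def test_expression_cutoffs(self, gene, value, mode, expected):
        assert classify_expression(value, gene, mode=mode) is expected

    def test_unconfigured_gene_errors(self):
        with pytest.raises(KeyError):
            classify_expression(1.0, "NOPE", mode="high")
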