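import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from reomet.diffexpr import (
    bh_adjust,
    binomial_direction_test,
    cv_filter,
    de_test,
    direction_concordance,
    enrich,
    proliferation_scores,
    significant,
    subtype_association,
)
from reomet.io_formats import GeneSetCollection


def bh_oracle(pvals):
    """Literal step-up: find largest i with p_(i) <= i*alpha/m by inverting."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * m / rank)
        adj[i] = running_min
    return adj


class TestBH:
    def test_stepup_hand_example(self):
        assert list(bh_adjust([0.01, 0.02, 0.03, 0.04])) == pytest.approx([0.04] * 4)

    def test_empty(self):
        assert bh_adjust([]).size == 0

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_oracle(self, pvals):
        assert list(bh_adjust(pvals)) == pytest.approx(bh_oracle(pvals))

    def test_fdr_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestCVFilter:
    def test_constant_gene_removed(self):
        frame = pd.DataFrame({"s1": [5.0, 9.0], "s2": [5.0, 11.0]}, index=["flat", "varies"])
        kept = cv_filter(frame, 0.10)
        assert "flat" not in kept

    def test_hand_arithmetic(self):
        # values {9, 11}: sample sd = sqrt(2), mean = 10, CV = 0.1414 > 0.10
        frame = pd.DataFrame({"s1": [9.0], "s2": [11.0]}, index=["g"])
        assert cv_filter(frame, 0.10) == ["g"]
        assert cv_filter(frame, 0.15) == []

    def test_zero_threshold_keeps_nonconstant(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.normal(10, 1, (20, 5)), index=[f"g{i}" for i in range(20)])
        assert len(cv_filter(frame, 0.0)) == 20

    def test_nonpositive_mean_excluded(self):
        frame = pd.DataFrame({"s1": [-5.0, 9.0], "s2": [-4.0, 11.0]}, index=["neg", "pos"])
        assert cv_filter(frame, 0.0) == ["pos"]


def _two_group_frame(rng, n_genes=50, n_per=10, shift_genes=(), delta=0.0):
    a_cols = [f"a{i}" for i in range(n_per)]
    b_cols = [f"b{i}" for i in range(n_per)]
    frame = pd.DataFrame(
        rng.normal(8.0, 1.0, (n_genes, 2 * n_per)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=a_cols + b_cols,
    )
    for g in shift_genes:
        frame.loc[g, a_cols] += delta
    return frame, a_cols, b_cols


class TestDETest:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(2)
        frame, a, b = _two_group_frame(rng)
        frame[b] = frame[a].to_numpy()
        results = de_test(frame, a, b)
        assert all(r.p > 0.99 for r in results)
        assert not significant(results)

    def test_label_swap_flips_directions_preserves_p(self):
        rng = np.random.default_rng(3)
        frame, a, b = _two_group_frame(rng, shift_genes=["g0", "g1"], delta=2.0)
        fwd = de_test(frame, a, b)
        rev = de_test(frame, b, a)
        for f, r in zip(fwd, rev):
            assert f.p == pytest.approx(r.p)
            assert f.direction != r.direction or f.mean_met == f.mean_nonmet

    def test_planted_shift_power(self):
        # delta = 2 sd in 100 of 1000 genes, n=50/50: recover >= 90 planted
        recovered = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            planted = [f"g{i}" for i in range(100)]
            frame, a, b = _two_group_frame(rng, n_genes=1000, n_per=50,
                                           shift_genes=planted, delta=2.0)
            sig = {r.gene_id for r in significant(de_test(frame, a, b))}
            recovered.append(len(sig & set(planted)))
        assert np.median(recovered) >= 90

    def test_zero_variance_both_groups_p_one(self):
        frame = pd.DataFrame(
            {"a0": [5.0], "a1": [5.0], "b0": [5.0], "b1": [5.0]}, index=["g"]
        )
        res = de_test(frame, ["a0", "a1"], ["b0", "b1"])
        assert res[0].p == 1.0

    def test_small_group_rejected(self):
        frame = pd.DataFrame({"a0": [1.0], "b0": [2.0], "b1": [2.0]}, index=["g"])
        with pytest.raises(ValueError):
            de_test(frame, ["a0"], ["b0", "b1"])


class TestConcordance:
    def test_all_concordant_significant(self):
        assert binomial_direction_test(468, 468) < 1e-4

    def test_forty_six_of_forty_eight(self):
        assert binomial_direction_test(46, 48) < 1e-4

    def test_exact_balance_p_one(self):
        assert binomial_direction_test(24, 48) == pytest.approx(1.0)

    def test_overlap_bookkeeping(self):
        from reomet.diffexpr import DEGene

        def g(gid, direction):
            return DEGene(gid, 1.0, 0.0, 1.0, 0.01, 0.01, direction)

        la = [g("x", "up_in_met"), g("y", "down_in_met"), g("z", "up_in_met")]
        lb = [g("x", "up_in_met"), g("y", "up_in_met"), g("w", "up_in_met")]
        res = direction_concordance(la, lb)
        assert res.overlap_count == 2
        assert res.same_direction_count == 1
        assert res.fraction == pytest.approx(0.5)

    def test_empty_overlap_flagged(self):
        from reomet.diffexpr import DEGene

        la = [DEGene("x", 1, 0, 1, 0.01, 0.01, "up_in_met")]
        lb = [DEGene("y", 1, 0, 1, 0.01, 0.01, "up_in_met")]
        res = direction_concordance(la, lb)
        assert res.overlap_count == 0
        assert np.isnan(res.fraction)


class TestProliferation:
    def test_constant_matrix(self):
        frame = pd.DataFrame(5.0, index=["g1", "g2"], columns=["s1", "s2", "s3"])
        scores, _ = proliferation_scores(frame, ["g1", "g2"])
        assert all(s.score == 5.0 for s in scores)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(4)
        frame, a, b = _two_group_frame(rng, n_genes=44, n_per=50)
        frame.loc[:, a] += 1.0
        scores, comparison = proliferation_scores(
            frame, list(frame.index), group_a=a, group_b=b
        )
        by_id = {s.sample_id: s.score for s in scores}
        diff = np.mean([by_id[s] for s in a]) - np.mean([by_id[s] for s in b])
        assert diff == pytest.approx(1.0, abs=0.15)
        assert comparison[1] < 0.01

    def test_missing_genes_tolerated(self):
        frame = pd.DataFrame(3.0, index=["g1"], columns=["s1", "s2"])
        scores, _ = proliferation_scores(frame, ["g1", "missing"])
        assert scores[0].score == 3.0

    def test_all_missing_rejected(self):
        frame = pd.DataFrame(3.0, index=["g1"], columns=["s1", "s2"])
        with pytest.raises(ValueError):
            proliferation_scores(frame, ["nope"])


class TestEnrich:
    def test_closed_form_extreme(self):
        # universe 10, set 5, query 5, overlap 5: p = 1/C(10,5)
        universe = [f"u{i}" for i in range(10)]
        sets = GeneSetCollection({"s": ("d", tuple(universe[:5]))})
        res = enrich(universe[:5], sets, universe)[0]
        assert res.p == pytest.approx(1 / 252, rel=1e-9)
        assert res.overlap == 5

    def test_disjoint_query_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        sets = GeneSetCollection({"s": ("d", tuple(universe[:5]))})
        res = enrich(universe[5:], sets, universe)[0]
        assert res.p == pytest.approx(1.0)

    def test_null_overlap_near_one(self):
        universe = [f"u{i}" for i in range(100)]
        sets = GeneSetCollection({"s": ("d", tuple(universe[:10]))})
        # query of 10 with expected overlap 1; observed 1 gives p well above alpha
        query = universe[:1] + universe[50:59]
        res = enrich(query, sets, universe)[0]
        assert res.p > 0.5

    def test_empty_universe_rejected(self):
        sets = GeneSetCollection({"s": ("d", ("a",))})
        with pytest.raises(ValueError):
            enrich(["a"], sets, [])


class TestSubtype:
    def test_null_p_uniform(self):
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(200):
            labels = rng.choice(["met", "nonmet"], 60)
            subtypes = rng.choice(["x", "y", "z"], 60)
            try:
                pvals.append(subtype_association(labels, subtypes)[1])
            except ValueError:
                continue
        ks_p = stats.kstest(pvals, "uniform").pvalue
        assert ks_p > 0.001

    def test_perfect_separation(self):
        labels = ["met"] * 50 + ["nonmet"] * 50
        subtypes = ["sq"] * 50 + ["br"] * 50
        stat, p = subtype_association(labels, subtypes)
        assert p < 1e-10

    def test_identical_rows_stat_zero(self):
        labels = ["met", "met", "nonmet", "nonmet"]
        subtypes = ["x", "y", "x", "y"]
        stat, p = subtype_association(labels, subtypes)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            subtype_association(["met", "nonmet"], ["x", "x"])
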