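import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reomet.io_formats import CNAMatrix, MutationMatrix, RegionGeneMap
from reomet.lesions import (
    binarize_cna,
    burden_compare,
    expr_cna_correlation,
    lesion_tests,
    prevalence_filter,
)


def _binary_frame(presence_by_lesion, samples):
    return pd.DataFrame(presence_by_lesion, index=samples).T.astype(int)


class TestPrevalenceFilter:
    def test_boundary_strictly_greater(self):
        samples = [f"s{i}" for i in range(100)]
        frame = _binary_frame(
            {
                "six": [1] * 6 + [0] * 94,
                "five": [1] * 5 + [0] * 95,
                "zero": [0] * 100,
            },
            samples,
        )
        kept = prevalence_filter(frame, 0.05)
        assert kept == ["six"]

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(40)]
        frame = pd.DataFrame(
            rng.binomial(1, 0.3, (8, 40)), index=[f"l{i}" for i in range(8)], columns=samples
        )
        base = set(prevalence_filter(frame, 0.2))
        shuffled = frame.iloc[rng.permutation(8), rng.permutation(40)]
        assert set(prevalence_filter(shuffled, 0.2)) == base


class TestBinarize:
    def test_amp_del_split(self):
        calls = pd.DataFrame(
            {"s1": [1, -1], "s2": [0, 1], "s3": [-1, 0]}, index=["r1", "r2"]
        )
        binary, sources = binarize_cna(CNAMatrix(calls))
        assert set(binary.index) == {"r1:amp", "r1:del", "r2:amp", "r2:del"}
        assert list(binary.loc["r1:amp"]) == [1, 0, 0]
        assert list(binary.loc["r1:del"]) == [0, 0, 1]
        assert sources["r1:amp"] == "r1"


class TestLesionTests:
    def test_reconstructed_mutation_contrast(self):
        # 201/315 vs 22/108 mutated: strongly higher in the metastatic group
        met = [f"m{i}" for i in range(315)]
        non = [f"n{i}" for i in range(108)]
        frame = _binary_frame(
            {"TP53_like": [1] * 201 + [0] * 114 + [1] * 22 + [0] * 86},
            met + non,
        )
        res = lesion_tests(frame, met, non, family="mutation", min_prevalence=0.05)[0]
        assert res.direction == "higher_in_met"
        assert res.freq_met == pytest.approx(201 / 315)
        assert res.freq_nonmet == pytest.approx(22 / 108)
        assert res.fisher_p < 1e-10

    def test_identical_frequencies_p_one(self):
        met = [f"m{i}" for i in range(20)]
        non = [f"n{i}" for i in range(20)]
        frame = _binary_frame({"l": [1] * 10 + [0] * 10 + [1] * 10 + [0] * 10}, met + non)
        res = lesion_tests(frame, met, non, min_prevalence=0.0)[0]
        assert res.fisher_p == pytest.approx(1.0)

    def test_matches_fisher_oracle(self):
        rng = np.random.default_rng(5)
        met = [f"m{i}" for i in range(15)]
        non = [f"n{i}" for i in range(12)]
        frame = pd.DataFrame(
            rng.binomial(1, 0.4, (6, 27)), index=[f"l{i}" for i in range(6)],
            columns=met + non,
        )
        for res in lesion_tests(frame, met, non, min_prevalence=0.0):
            vals = frame.loc[res.lesion_id]
            a = int(vals[met].sum())
            c = int(vals[non].sum())
            _, expected = stats.fisher_exact([[a, 15 - a], [c, 12 - c]])
            assert res.fisher_p == pytest.approx(expected, abs=1e-12)

    def test_planted_lesion_recovery(self):
        # f_met=0.4 vs f_nonmet=0.1 at n=300/100: recovered in >=95% of 20 seeds
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            met = [f"m{i}" for i in range(300)]
            non = [f"n{i}" for i in range(100)]
            data = {"planted": np.concatenate([
                rng.binomial(1, 0.4, 300), rng.binomial(1, 0.1, 100)])}
            for j in range(10):
                data[f"bg{j}"] = rng.binomial(1, 0.1, 400)
            frame = pd.DataFrame(data, index=met + non).T
            results = {r.lesion_id: r for r in lesion_tests(frame, met, non, min_prevalence=0.05)}
            if "planted" in results and results["planted"].fdr < 0.05:
                hits += 1
        assert hits >= 19

    def test_empty_group_rejected(self):
        frame = _binary_frame({"l": [1, 0]}, ["a", "b"])
        with pytest.raises(ValueError):
            lesion_tests(frame, ["a", "b"], ["zzz"])


class TestBurden:
    def test_median_arithmetic(self):
        met = ["m1", "m2", "m3"]
        non = ["n1", "n2", "n3"]
        frame = pd.DataFrame(
            np.array([[1] * 80 + [0] * 20] * 3 + [[1] * 44 + [0] * 56] * 3).T,
            columns=met + non,
        )
        res = burden_compare(frame, met, non)
        assert res.median_met == 80
        assert res.median_nonmet == 44

    def test_identical_groups_p_near_one(self):
        cols = [f"s{i}" for i in range(8)]
        frame = pd.DataFrame(np.ones((5, 8), dtype=int), columns=cols)
        res = burden_compare(frame, cols[:4], cols[4:])
        assert res.p == pytest.approx(1.0)

    def test_poisson_separation(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            met = [f"m{i}" for i in range(100)]
            non = [f"n{i}" for i in range(100)]
            # per-sample totals ~ Poisson(80) vs Poisson(44) via many rare lesions
            counts = np.concatenate([rng.poisson(80, 100), rng.poisson(44, 100)])
            n_lesions = 200
            frame = pd.DataFrame(0, index=range(n_lesions), columns=met + non)
            for j, total in enumerate(counts):
                idx = rng.choice(n_lesions, size=min(total, n_lesions), replace=False)
                frame.iloc[idx, j] = 1
            res = burden_compare(frame, met, non)
            if res.p < 0.001:
                hits += 1
        assert hits >= 19


class TestExprCnaCorrelation:
    def _cna(self, rows, samples):
        return CNAMatrix(pd.DataFrame(rows, index=samples).T.astype(int))

    def test_monotone_dosage_rho_one(self):
        # expression a strictly increasing function of the call (ties aligned)
        samples = [f"s{i}" for i in range(12)]
        cn = [-1] * 4 + [0] * 4 + [1] * 4
        calls = self._cna({"g1": cn}, samples)
        expr = pd.DataFrame({"g1": [5.0 + 2.0 * v for v in cn]}, index=samples).T
        res = expr_cna_correlation(expr, calls)[0]
        assert res.rho == pytest.approx(1.0)

    def test_strictly_increasing_expression_rho_positive(self):
        samples = [f"s{i}" for i in range(12)]
        calls = self._cna({"g1": [-1] * 4 + [0] * 4 + [1] * 4}, samples)
        expr = pd.DataFrame({"g1": np.arange(12, dtype=float)}, index=samples).T
        res = expr_cna_correlation(expr, calls)[0]
        assert res.rho > 0.9  # < 1 only because the call vector is tied

    def test_brute_force_rank_oracle(self):
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(11)]
        cn = rng.integers(-1, 2, 11)
        while len(set(cn)) < 2:
            cn = rng.integers(-1, 2, 11)
        ex = rng.normal(size=11)
        calls = self._cna({"g1": cn}, samples)
        expr = pd.DataFrame({"g1": ex}, index=samples).T
        res = expr_cna_correlation(expr, calls)[0]
        # independent oracle: Pearson on midranks
        rank_ex = pd.Series(ex).rank().to_numpy()
        rank_cn = pd.Series(cn).rank().to_numpy()
        expected = np.corrcoef(rank_ex, rank_cn)[0, 1]
        assert res.rho == pytest.approx(expected, abs=1e-12)

    def test_independent_null_not_significant(self):
        sig_flags = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            samples = [f"s{i}" for i in range(50)]
            cn = rng.integers(-1, 2, 50)
            calls = self._cna({"g1": cn}, samples)
            expr = pd.DataFrame({"g1": rng.normal(size=50)}, index=samples).T
            res = expr_cna_correlation(expr, calls)[0]
            sig_flags.append(res.positive_significant)
        assert sum(sig_flags) <= 2

    def test_constant_cna_skipped(self):
        samples = [f"s{i}" for i in range(12)]
        calls = self._cna({"g1": [0] * 12, "g2": [1] * 6 + [0] * 6}, samples)
        expr = pd.DataFrame(
            {"g1": np.arange(12.0), "g2": np.arange(12.0)}, index=samples
        ).T
        res = expr_cna_correlation(expr, calls)
        assert [r.gene_id for r in res] == ["g2"]

    def test_region_mapping(self):
        samples = [f"s{i}" for i in range(12)]
        calls = self._cna({"regA": [1] * 6 + [0] * 6}, samples)
        expr = pd.DataFrame(
            {"memberGene": [2.0] * 6 + [1.0] * 6}, index=samples
        ).T
        rmap = RegionGeneMap({"regA": ("memberGene",)})
        res = expr_cna_correlation(expr, calls, rmap)[0]
        assert res.gene_id == "memberGene"
        assert res.rho > 0.9

    def test_too_few_shared_samples(self):
        samples = [f"s{i}" for i in range(5)]
        calls = self._cna({"g1": [1, 0, 1, 0, 1]}, samples)
        expr = pd.DataFrame({"g1": np.arange(5.0)}, index=samples).T
        with pytest.raises(ValueError):
            expr_cna_correlation(expr, calls)


class TestDirectionProperty:
    def test_all_planted_higher_in_met(self, default_cohort):
        cohort = default_cohort
        latent = cohort.latent_met
        met = [s for s in latent.index if latent[s] == 1]
        non = [s for s in latent.index if latent[s] == 0]
        results = lesion_tests(cohort.mutations, met, non, min_prevalence=0.05)
        sig = [r for r in results if r.fdr < 0.05]
        assert sig, "expected planted mutations to reach significance"
        assert all(r.direction == "higher_in_met" for r in sig)
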