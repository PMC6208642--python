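import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from pneumotype import (
    ClinicalTable,
    adjust_p,
    chisq_events,
    codetection_test,
    fisher_exact_rxc,
    kruskal_wallis,
    mann_whitney,
    run_feature_screen,
    spearman,
)


def _brute_fisher(table: np.ndarray) -> float:
    """Independent enumeration oracle: iterate every candidate table via
    cell-wise itertools.product and keep those with matching margins."""
    table = np.asarray(table, int)
    row, col = table.sum(1), table.sum(0)
    N = table.sum()
    const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(N + 1)

    def logp(t):
        return const - gammaln(np.asarray(t) + 1).sum()

    obs = logp(table)
    shape = table.shape
    ranges = [range(min(row[i // shape[1]], col[i % shape[1]]) + 1)
              for i in range(table.size)]
    total = 0.0
    for cells in itertools.product(*ranges):
        t = np.asarray(cells).reshape(shape)
        if (t.sum(1) == row).all() and (t.sum(0) == col).all():
            lp = logp(t)
            if lp <= obs + 1e-7:
                total += np.exp(lp)
    return min(total, 1.0)


class TestFisherExact:
    def test_hand_value_3113(self):
        res = fisher_exact_rxc([[3, 1], [1, 3]])
        assert res.p == pytest.approx(0.485714285, abs=1e-8)

    def test_perfect_separation_5x5(self):
        res = fisher_exact_rxc([[5, 0], [0, 5]])
        assert res.p == pytest.approx(2 / 252, abs=1e-12)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact_rxc([[4, 2], [4, 2]]).p == pytest.approx(1.0)

    def test_zero_margin_noted(self):
        res = fisher_exact_rxc([[0, 0], [3, 5]])
        assert res.p == 1.0 and "zero margin" in res.note

    def test_matches_scipy_on_random_2x2(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            t = rng.integers(0, 10, size=(2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            ours = fisher_exact_rxc(t).p
            ref = ss.fisher_exact(t).pvalue
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_matches_brute_oracle_on_random_2x3(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            t = rng.integers(0, 6, size=(2, 3))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert fisher_exact_rxc(t).p == \
                pytest.approx(_brute_fisher(t), abs=1e-9)

    def test_monte_carlo_agrees_with_enumeration(self):
        t = [[8, 2, 4], [3, 9, 5]]
        exact = fisher_exact_rxc(t).p
        mc = fisher_exact_rxc(t, max_enumeration_total=1, seed=0).p
        assert mc == pytest.approx(exact, abs=0.01)
        assert "monte carlo" in fisher_exact_rxc(
            t, max_enumeration_total=1, seed=0).note

    def test_rejects_bad_tables(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc([[1, 2]])
        with pytest.raises(ValueError):
            fisher_exact_rxc([[1, -2], [0, 3]])


class TestChisqEvents:
    def test_two_group_hand_value(self):
        res = chisq_events([10, 0], [1, 1])
        assert res.statistic == pytest.approx(10.0)
        assert res.p == pytest.approx(0.001565, abs=1e-6)

    def test_events_proportional_to_exposure(self):
        res = chisq_events([10, 20, 30], [1, 2, 3])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_low_expected_flagged(self):
        res = chisq_events([1, 1], [1, 99])
        assert "expected count" in res.note

    def test_guards(self):
        with pytest.raises(ValueError):
            chisq_events([0, 0], [1, 1])
        with pytest.raises(ValueError):
            chisq_events([1, 1], [0, 1])


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_value_no_ties(self):
        res = kruskal_wallis([[1, 2, 3], [10, 11, 12], [20, 21, 22]])
        assert res.statistic == pytest.approx(7.2)
        assert res.p == pytest.approx(np.exp(-3.6), rel=1e-6)

    def test_monotone_transform_invariance(self):
        groups = [[1.0, 3.0, 9.0], [2.0, 8.0], [0.5, 5.0]]
        a = kruskal_wallis(groups)
        b = kruskal_wallis([[np.log(v) for v in g] for g in groups])
        assert a.statistic == pytest.approx(b.statistic)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            groups = [rng.integers(0, 6, size=rng.integers(3, 8)).astype(float)
                      for _ in range(3)]
            if np.all(np.concatenate(groups) == groups[0][0]):
                continue
            ours = kruskal_wallis(groups)
            ref = ss.kruskal(*groups)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-9)


class TestMannWhitney:
    def test_complete_separation_exact(self):
        res = mann_whitney([1, 2, 3], [10, 11, 12])
        assert res.p == pytest.approx(0.1)  # 2/C(6,3) tail doubling

    def test_equal_multisets(self):
        res = mann_whitney([1, 2, 2, 9, 9, 9, 9], [2, 1, 9, 9, 2, 9, 9])
        assert res.p == 1.0

    def test_symmetry(self):
        x, y = [1.5, 2.5, 9.0, 4.0], [3.0, 8.0, 8.5]
        assert mann_whitney(x, y).p == pytest.approx(mann_whitney(y, x).p)

    def test_matches_scipy_exact_no_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(2, 6))
            m = int(rng.integers(2, 6))
            vals = rng.permutation(100)[:n + m].astype(float)
            x, y = vals[:n], vals[n:]
            ours = mann_whitney(x, y)
            ref = ss.mannwhitneyu(x, y, alternative="two-sided",
                                  method="exact")
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_matches_scipy_normal_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            x = rng.integers(0, 5, size=12).astype(float)
            y = rng.integers(0, 5, size=15).astype(float)
            if len(np.unique(np.concatenate([x, y]))) == 1:
                continue
            ours = mann_whitney(x, y)
            ref = ss.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic", use_continuity=True)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-9)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).statistic == \
            pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2]).statistic == \
            pytest.approx(-1.0)

    def test_hand_rho(self):
        res = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert res.statistic == pytest.approx(0.8)

    def test_exact_p_matches_direct_enumeration(self):
        rng = np.random.default_rng(12)
        x = rng.permutation(7).astype(float)
        y = rng.permutation(7).astype(float)
        res = spearman(x, y)
        # independent oracle: enumerate all 7! pairings directly
        rx = ss.rankdata(x)
        obs = abs(np.corrcoef(rx, ss.rankdata(y))[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ss.rankdata(y)):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        assert res.p == pytest.approx(count / total, abs=1e-12)

    def test_t_approximation_matches_scipy_large_n(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        res = spearman(x, y)
        ref = ss.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_variance_flagged(self):
        res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(res.statistic) and "zero variance" in res.note


class TestAdjustP:
    def test_bh_step_up_hand_example(self):
        out = adjust_p([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(out, 0.04)

    def test_all_equal_stay_equal(self):
        out = adjust_p([0.3, 0.3, 0.3], "bh")
        assert np.allclose(out, out[0])

    def test_bh_dominates_raw_and_q_below_bh(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(1e-6, 1, size=50)
        bh = adjust_p(p, "bh")
        q = adjust_p(p, "qvalue")
        assert np.all(bh >= p - 1e-15)
        assert np.all(q <= bh + 1e-15)

    def test_bh_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(1e-6, 1, size=40)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adjust_p(p, "bh"), ref, atol=1e-12)

    def test_pi0_capped_at_one(self):
        p = np.full(10, 0.9)  # every p above lambda=0.5
        q = adjust_p(p, "qvalue")
        assert np.allclose(q, adjust_p(p, "bh"))

    def test_empty_input(self):
        assert adjust_p([], "bh").size == 0


class TestRankTestCalibration:
    def test_type_one_error_near_nominal(self):
        # null Gaussian data; rejection rate at 0.05 should sit inside the
        # binomial band for both rank tests
        rng = np.random.default_rng(17)
        n_rep = 5000
        rej_kw = rej_mwu = 0
        for _ in range(n_rep):
            g = [rng.normal(size=8) for _ in range(3)]
            rej_kw += kruskal_wallis(g).p < 0.05
            rej_mwu += mann_whitney(rng.normal(size=14),
                                    rng.normal(size=14)).p < 0.05
        assert 0.035 <= rej_kw / n_rep <= 0.065
        assert 0.035 <= rej_mwu / n_rep <= 0.065


class TestFeatureScreen:
    def _clinical(self, labels, rng):
        n = len(labels)
        smear_p = np.array([0.8, 0.0, 0.8])[labels]
        data = pd.DataFrame({
            "smear": np.where(rng.random(n) < smear_p, "Positive", "negative"),
            "lymphocyte_pct": rng.normal(20, 5, size=n),
            "exacerbations": rng.poisson(np.array([0.4, 2.0, 3.5])[labels]),
        }, index=[f"s{i}" for i in range(n)])
        return ClinicalTable(data=data, types={
            "smear": "categorical",
            "lymphocyte_pct": "continuous",
            "exacerbations": "event-count",
        })

    def test_dispatch_and_planted_smear_detected(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1, 2], [16, 16, 8])
        rep = run_feature_screen(self._clinical(labels, rng), labels)
        res = rep.results
        assert res.loc["smear", "test"] == "fisher_exact"
        assert res.loc["lymphocyte_pct", "test"] == "kruskal_wallis"
        assert res.loc["exacerbations", "test"] == "chisq_events"
        assert res.loc["smear", "p"] < 0.05
        # lymphocytes were generated independently of the labels
        assert res.loc["lymphocyte_pct", "p"] > 0.01

    def test_missing_values_dropped_with_n_reported(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        data = pd.DataFrame({
            "lymphocyte_pct": [1.0, 2.0, np.nan, 10.0, 11.0, 12.0],
        }, index=[f"s{i}" for i in range(6)])
        ct = ClinicalTable(data=data, types={"lymphocyte_pct": "continuous"})
        rep = run_feature_screen(ct, labels)
        assert rep.results.loc["lymphocyte_pct", "n"] == 5

    def test_unknown_feature_type_rejected(self):
        data = pd.DataFrame({"x": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="unknown feature type"):
            ClinicalTable(data=data, types={"x": "ordinal"})

    def test_null_feature_rejection_rate_calibrated(self):
        rng = np.random.default_rng(3)
        labels = np.repeat([0, 1, 2], 10)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            data = pd.DataFrame({"v": rng.normal(size=30)},
                                index=[f"s{i}" for i in range(30)])
            ct = ClinicalTable(data=data, types={"v": "continuous"})
            hits += run_feature_screen(ct, labels).results.loc["v", "p"] < 0.05
        # binomial(400, 0.05): ~3 sd band
        assert 0.02 <= hits / n_rep <= 0.09


class TestCodetection:
    def _presence(self, mat, samples=None):
        mat = np.asarray(mat, bool)
        return pd.DataFrame(
            mat, index=[f"t{i}" for i in range(mat.shape[0])],
            columns=samples or [f"s{i}" for i in range(mat.shape[1])])

    def test_absent_taxa_give_p_one(self):
        pres = self._presence(np.zeros((3, 8)))
        res = codetection_test(pres, ["t0", "t1"], ["s0", "s1"], B=99)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_group_specific_codetection_significant(self):
        mat = np.zeros((4, 30), bool)
        mat[:2, :15] = True  # both taxa present exactly in the group
        pres = self._presence(mat)
        group = [f"s{i}" for i in range(15)]
        res = codetection_test(pres, ["t0", "t1"], group, B=9999, seed=0)
        assert res.p <= 0.01

    def test_group_size_guard(self):
        pres = self._presence(np.ones((2, 3)))
        with pytest.raises(ValueError, match="larger"):
            codetection_test(pres, ["t0"], ["a", "b", "c", "d"])
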