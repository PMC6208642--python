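import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon
from scipy.special import gammaln
from scipy.stats import dirichlet_multinomial
from sklearn.metrics import adjusted_rand_score

from pneumotype import (
    AbundanceTable,
    CommunityConfig,
    calinski_harabasz,
    core_microbes,
    dmm_fit,
    dmm_select_K,
    generate_community,
    jsd_distance,
    method_agreement,
    pam,
    pcoa_coordinates,
    select_k_pam,
    to_relative,
)
from pneumotype.stratify import ClusteringResult, DistanceMatrix, dm_logpmf
from pneumotype.synthio import default_alphas


def _dist_from_matrix(D):
    return DistanceMatrix(ids=[f"s{i}" for i in range(len(D))],
                          values=np.asarray(D, float), metric="test")


def _rel_df(cols):
    df = pd.DataFrame(cols)
    return df / df.sum(axis=0)


class TestJSD:
    def test_self_distance_zero(self):
        rel = _rel_df({"a": [0.5, 0.5], "b": [0.5, 0.5]})
        d = jsd_distance(rel)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_supports_maximal(self):
        rel = _rel_df({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        d = jsd_distance(rel)
        assert d.values[0, 1] == pytest.approx(np.sqrt(np.log(2)), abs=1e-12)

    def test_hand_value(self):
        rel = _rel_df({"a": [0.5, 0.5], "b": [0.25, 0.75]})
        d = jsd_distance(rel)
        assert d.values[0, 1] == pytest.approx(0.1839, abs=2e-4)

    def test_matches_scipy_oracle_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            p = rng.dirichlet(np.ones(8))
            q = rng.dirichlet(np.ones(8))
            d = jsd_distance(_rel_df({"a": p, "b": q}))
            assert d.values[0, 1] == pytest.approx(
                jensenshannon(p, q, base=np.e), abs=1e-10)

    def test_rejects_unnormalised_columns(self):
        with pytest.raises(ValueError, match="normalised"):
            jsd_distance(pd.DataFrame({"a": [0.2, 0.2]}))

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            P = rng.dirichlet(rng.uniform(0.2, 3.0, size=6), size=3).T
            d = jsd_distance(pd.DataFrame(P, columns=list("abc"))).values
            for i, j, k in itertools.permutations(range(3), 3):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestPAM:
    def test_k_equals_n_zero_cost(self):
        rng = np.random.default_rng(0)
        X = rng.random((4, 4))
        D = np.triu(X, 1)
        D = D + D.T
        res = pam(_dist_from_matrix(D), 4)
        assert sorted(res.medoids) == sorted(res.ids)

    def test_two_tight_pairs_recovered(self):
        D = np.array([
            [0, 0.1, 5, 5],
            [0.1, 0, 5, 5],
            [5, 5, 0, 0.1],
            [5, 5, 0.1, 0],
        ], float)
        res = pam(_dist_from_matrix(D), 2)
        assert res.labels[0] == res.labels[1]
        assert res.labels[2] == res.labels[3]
        assert res.labels[0] != res.labels[2]

    def test_matches_exhaustive_search_small_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(5, 9))
            k = int(rng.integers(2, 4))
            X = rng.random((n, n))
            D = np.triu(X, 1)
            D = D + D.T
            dist = _dist_from_matrix(D)
            res = pam(dist, k)
            med = [dist.ids.index(m) for m in res.medoids]
            cost = D[med].min(axis=0).sum()
            best = min(D[list(subset)].min(axis=0).sum()
                       for subset in itertools.combinations(range(n), k))
            assert cost == pytest.approx(best, abs=1e-9)

    def test_k_out_of_range(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError):
            pam(_dist_from_matrix(D), 1)
        with pytest.raises(ValueError):
            pam(_dist_from_matrix(D), 4)


class TestCalinskiHarabasz:
    def test_label_permutation_invariance(self, planted):
        labels = planted["labels"]
        perm = np.array([2, 0, 1])[labels]
        assert calinski_harabasz(planted["dist"], labels) == \
            pytest.approx(calinski_harabasz(planted["dist"], perm))

    def test_hand_computed_toy(self):
        # 6 points, two clusters of 3; within distances 1, across 4
        D = np.full((6, 6), 4.0)
        for block in (slice(0, 3), slice(3, 6)):
            D[block, block] = 1.0
        np.fill_diagonal(D, 0.0)
        labels = [0, 0, 0, 1, 1, 1]
        # cluster medoid = first point of each block; global medoid = point 0
        # between = 3*d(0,0)^2 + 3*d(3,0)^2 = 48; within = 2*1 + 2*1 = 4
        # CH = (48/1) / (4/4) = 48
        assert calinski_harabasz(_dist_from_matrix(D), labels) == \
            pytest.approx(48.0)

    def test_zero_within_gives_max_float(self):
        D = np.array([[0, 0, 3, 3], [0, 0, 3, 3],
                      [3, 3, 0, 0], [3, 3, 0, 0]], float)
        ch = calinski_harabasz(_dist_from_matrix(D), [0, 0, 1, 1])
        assert ch == np.finfo(float).max

    def test_degenerate_k_returns_nan(self, planted):
        n = planted["dist"].n
        assert np.isnan(calinski_harabasz(planted["dist"], np.zeros(n, int)))
        assert np.isnan(calinski_harabasz(planted["dist"], np.arange(n)))


class TestSelectK:
    def test_planted_three_components_chosen(self, planted):
        res = select_k_pam(planted["dist"])
        assert res.k == 3
        assert adjusted_rand_score(planted["labels"], res.labels) >= 0.9

    def test_two_components(self):
        table, labels = generate_community(
            CommunityConfig(K=2, mixing=np.array([0.5, 0.5]), seed=5))
        res = select_k_pam(jsd_distance(to_relative(table)))
        assert res.k == 2

    def test_index_table_covers_range(self, planted):
        res = select_k_pam(planted["dist"], range(2, 5))
        assert list(res.index_table.index) == [2, 3, 4]


class TestDMM:
    def test_logpmf_single_taxon_is_zero(self):
        X = np.array([[7.0], [3.0]])
        assert np.allclose(dm_logpmf(X, np.array([2.5])), 0.0)

    def test_logpmf_hand_value(self):
        # x = (2,1), alpha = (1,1):
        # lnG(2) - lnG(5) + lnG(3) - lnG(1) + lnG(2) - lnG(1) = ln(2/24)
        val = dm_logpmf(np.array([[2.0, 1.0]]), np.array([1.0, 1.0]))[0]
        assert val == pytest.approx(np.log(2 / 24), abs=1e-12)

    def test_logpmf_matches_scipy_dirichlet_multinomial(self):
        # scipy includes the multinomial coefficient; remove it to compare
        rng = np.random.default_rng(3)
        for _ in range(20):
            T = int(rng.integers(2, 6))
            alpha = rng.uniform(0.2, 5.0, size=T)
            x = rng.integers(0, 20, size=T).astype(float)
            n = x.sum()
            if n == 0:
                continue
            ours = dm_logpmf(x[None, :], alpha)[0]
            coeff = gammaln(n + 1) - gammaln(x + 1).sum()
            ref = dirichlet_multinomial.logpmf(x, alpha, n)
            assert ours + coeff == pytest.approx(ref, abs=1e-9)

    def test_em_loglik_monotone(self, planted):
        model = dmm_fit(planted["table"], K=3, n_restarts=1, seed=0)
        diffs = np.diff(model.loglik_trace)
        assert np.all(diffs >= -1e-8)

    def test_planted_labels_recovered(self, planted):
        model = dmm_fit(planted["table"], K=3, n_restarts=2, seed=0)
        ari = adjusted_rand_score(planted["labels"], model.labels())
        assert ari >= 0.9
        assert np.allclose(model.resp.sum(axis=1), 1.0)
        assert model.pi.sum() == pytest.approx(1.0)

    def test_alpha_direction_recovery(self):
        # K=2, T=10, n=200 at default separation: estimated alpha direction
        # within L1 0.1 of the truth for each component
        alpha = default_alphas(2, 10)
        cfg = CommunityConfig(n_samples=200, n_taxa=10, K=2,
                              mixing=np.array([0.5, 0.5]), alpha=alpha,
                              seed=9)
        table, labels = generate_community(cfg)
        model = dmm_fit(table, K=2, n_restarts=2, seed=1)
        truth = alpha / alpha.sum(axis=1, keepdims=True)
        est = model.alpha / model.alpha.sum(axis=1, keepdims=True)
        # match components by nearest direction
        errs = [min(np.abs(est[j] - truth[i]).sum() for j in range(2))
                for i in range(2)]
        assert max(errs) < 0.1

    def test_select_K_planted_and_null(self, planted):
        res = dmm_select_K(planted["table"], range(1, 6), n_restarts=2, seed=0)
        assert res.k == 3
        null_table, _ = generate_community(
            CommunityConfig(n_samples=25, K=1, seed=12))
        null = dmm_select_K(null_table, range(1, 4), n_restarts=2, seed=0)
        assert null.k == 1

    def test_K_exceeding_n_rejected(self, planted):
        with pytest.raises(ValueError, match="exceeds"):
            dmm_fit(planted["table"], K=99)


class TestMethodAgreement:
    def _res(self, labels, ids=None):
        labels = np.asarray(labels)
        ids = ids or [f"s{i}" for i in range(len(labels))]
        return ClusteringResult(method="pam", ids=ids, labels=labels,
                                k=int(labels.max()) + 1)

    def test_identical_labelings(self):
        a = self._res([0, 0, 1, 1, 2, 2])
        out = method_agreement(a, self._res([0, 0, 1, 1, 2, 2]))
        assert out["n_mismatched"] == 0 and out["ari"] == 1.0

    def test_permuted_labels_still_agree(self):
        out = method_agreement(self._res([0, 0, 1, 1]),
                               self._res([1, 1, 0, 0]))
        assert out["n_mismatched"] == 0 and out["ari"] == 1.0

    def test_one_flipped_sample(self):
        out = method_agreement(self._res([0, 0, 0, 1, 1, 1]),
                               self._res([0, 0, 1, 1, 1, 1]))
        assert out["n_mismatched"] == 1

    def test_random_labels_near_zero_ari(self, planted):
        rng = np.random.default_rng(8)
        ids = planted["dist"].ids
        rand = rng.integers(0, 3, size=len(ids))
        out = method_agreement(
            self._res(planted["labels"], ids), self._res(rand, ids))
        assert abs(out["ari"]) < 0.15

    def test_different_sample_sets_rejected(self):
        a = self._res([0, 1], ids=["x", "y"])
        b = self._res([0, 1], ids=["x", "z"])
        with pytest.raises(ValueError, match="sample sets"):
            method_agreement(a, b)


class TestCoreMicrobes:
    def test_planted_cores_disjoint_and_anticorrelated(self, planted):
        out = core_microbes(planted["rel"], planted["labels"])
        sets = [set(v) for v in out["cores"].values()]
        for a, b in itertools.combinations(sets, 2):
            assert not (a & b)
        between = out["pairs"][out["pairs"]["kind"] == "between"]
        within = out["pairs"][out["pairs"]["kind"] == "within"]
        # compositional closure: dominant taxa of different subgroups
        # trade off; co-dominant taxa of one subgroup rise together
        assert (between["rho"] < 0).mean() > 0.8
        assert (within["rho"] > 0).all()
        assert (within["p"] < 0.01).all()

    def test_single_component_between_not_applicable(self):
        table, labels = generate_community(
            CommunityConfig(n_samples=12, K=1, seed=2,
                            alpha=np.ones((1, 10)) * 5, n_taxa=10))
        out = core_microbes(to_relative(table), labels, min_mean=0.0)
        assert "between_note" in out["pairs"].attrs

    def test_no_qualifying_taxon_warns(self, planted):
        with pytest.warns(UserWarning, match="no qualifying"):
            core_microbes(planted["rel"], planted["labels"], min_mean=0.99)


def test_pcoa_separates_planted_components(planted):
    coords = pcoa_coordinates(planted["dist"])
    assert coords.shape == (planted["dist"].n, 2)
    # between-component centroid spread exceeds within-component spread
    labels = planted["labels"]
    cents = np.stack([coords[labels == c].mean(axis=0) for c in range(3)])
    within = max(coords[labels == c].std(axis=0).max() for c in range(3))
    between = np.linalg.norm(cents[0] - cents[1])
    assert between > within
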