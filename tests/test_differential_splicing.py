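"""Dirichlet-multinomial likelihood, LRT behaviour and FDR handling."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import gammaln

from conftest import make_matrix
from crypticsplice.differential_splicing import (
    differential_splicing,
    dm_loglik,
    estimate_concentration,
    fit_cluster,
)
from crypticsplice.junction_clustering import cluster_junctions


def dm_pmf_reference(x, alpha):
    """Direct beta-function formula for the DM pmf (independent oracle)."""
    n = sum(x)
    log_coef = math.lgamma(n + 1) - sum(math.lgamma(xi + 1) for xi in x)
    log_beta = (
        math.lgamma(sum(alpha)) - math.lgamma(n + sum(alpha))
        + sum(math.lgamma(xi + ai) - math.lgamma(ai) for xi, ai in zip(x, alpha))
    )
    return math.exp(log_coef + log_beta)


class TestDmLoglik:
    def test_multinomial_limit_single_draw(self):
        # one trial: DM -> categorical regardless of concentration scale
        ll = dm_loglik(np.array([[1, 0]]), np.array([0.5, 0.5]), 1e6)
        assert ll == pytest.approx(math.log(0.5), abs=1e-4)

    def test_matches_beta_function_oracle(self):
        # frozen from dm_pmf_reference((2,2), (1,1)) = C(4,2)*B-ratio = 0.2
        ll = dm_loglik(np.array([[2, 2]]), np.array([0.5, 0.5]), 2.0)
        assert ll == pytest.approx(math.log(0.2), rel=1e-10)
        assert dm_pmf_reference((2, 2), (1.0, 1.0)) == pytest.approx(0.2)

    @pytest.mark.parametrize("counts,props,conc", [
        ((3, 1, 0), (0.5, 0.3, 0.2), 7.5),
        ((10, 2, 5), (0.2, 0.2, 0.6), 0.8),
        ((0, 0, 4), (0.1, 0.1, 0.8), 50.0),
    ])
    def test_agrees_with_reference_pmf(self, counts, props, conc):
        alpha = [conc * p for p in props]
        expected = math.log(dm_pmf_reference(counts, alpha))
        assert dm_loglik(np.array([counts]), np.array(props), conc) \
            == pytest.approx(expected, rel=1e-9)

    def test_sums_to_one_over_small_support(self):
        # DM is a proper distribution: sum of pmf over all count vectors
        conc, n, J = 3.0, 4, 3
        props = np.array([0.5, 0.3, 0.2])
        total = 0.0
        for x in itertools.product(range(n + 1), repeat=J):
            if sum(x) == n:
                total += math.exp(dm_loglik(np.array([x]), props, conc))
        assert total == pytest.approx(1.0, rel=1e-9)

    def test_junction_permutation_invariance(self):
        counts = np.array([[5, 2, 9], [1, 7, 3]])
        props = np.array([0.5, 0.2, 0.3])
        perm = [2, 0, 1]
        assert dm_loglik(counts, props, 4.0) == pytest.approx(
            dm_loglik(counts[:, perm], props[perm], 4.0)
        )

    def test_multinomial_limit_large_concentration(self):
        counts = np.array([[40, 25, 35]])
        props = np.array([0.4, 0.25, 0.35])
        n = counts.sum()
        log_multinomial = (
            gammaln(n + 1) - gammaln(counts + 1).sum()
            + (counts * np.log(props)).sum()
        )
        assert dm_loglik(counts, props, 1e6) == pytest.approx(
            float(log_multinomial), rel=1e-4
        )

    def test_zero_total_sample_contributes_nothing(self):
        with_empty = dm_loglik(np.array([[3, 2], [0, 0]]), np.array([0.5, 0.5]), 5.0)
        without = dm_loglik(np.array([[3, 2]]), np.array([0.5, 0.5]), 5.0)
        assert with_empty == pytest.approx(without)


class TestFitCluster:
    def test_identical_groups_give_null_result(self):
        counts = np.array([[50, 50, 50, 50], [150, 150, 150, 150]])
        r = fit_cluster(counts, ["a", "a", "b", "b"])
        assert r.lrt_stat == pytest.approx(0.0, abs=0.05)
        assert r.p_value > 0.9

    def test_planted_usage_flip_detected(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(20):
            a = np.array([rng.multinomial(200, rng.dirichlet(50 * np.array([0.9, 0.1])))
                          for _ in range(3)])
            b = np.array([rng.multinomial(200, rng.dirichlet(50 * np.array([0.1, 0.9])))
                          for _ in range(3)])
            counts = np.vstack([a, b]).T
            ps.append(fit_cluster(counts, ["c"] * 3 + ["k"] * 3).p_value)
        assert np.median(ps) < 1e-3

    def test_invariant_to_relabeling_within_groups_and_junction_order(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(5, 200, size=(3, 6))
        labels = ["c", "c", "c", "k", "k", "k"]
        base = fit_cluster(counts, labels, concentration=30.0)
        swapped = fit_cluster(counts[:, [1, 0, 2, 5, 4, 3]], labels, concentration=30.0)
        permuted = fit_cluster(counts[[2, 0, 1], :], labels, concentration=30.0)
        assert base.lrt_stat == pytest.approx(swapped.lrt_stat, abs=1e-4)
        assert base.lrt_stat == pytest.approx(permuted.lrt_stat, abs=1e-4)

    def test_group_without_reads_flagged_untestable(self):
        counts = np.array([[10, 10, 0, 0], [20, 20, 0, 0]])
        r = fit_cluster(counts, ["a", "a", "b", "b"])
        assert r.failed

    def test_requires_two_groups(self):
        with pytest.raises(ValueError, match="two groups"):
            fit_cluster(np.array([[1, 2], [3, 4]]), ["a", "a"])

    def test_df_is_junctions_minus_one(self):
        rng = np.random.default_rng(2)
        for J in (2, 3, 5):
            counts = rng.integers(10, 100, size=(J, 4))
            r = fit_cluster(counts, ["a", "a", "b", "b"])
            assert r.df == J - 1


class TestConcentrationEstimator:
    def test_recovers_known_concentration(self):
        rng = np.random.default_rng(0)
        usage = np.array([0.5, 0.3, 0.2])
        ests = []
        for _ in range(200):
            X = np.array([rng.multinomial(500, rng.dirichlet(50 * usage))
                          for _ in range(6)]).T
            ests.append(estimate_concentration(X))
        assert 35 < np.median(ests) < 70

    def test_underdispersed_counts_hit_upper_bound(self):
        # identical samples: no between-sample variance at all
        X = np.tile(np.array([[100], [200]]), (1, 4))
        assert estimate_concentration(X) > 1e6


class TestDifferentialSplicing:
    def _matrix_two_clusters(self):
        juncs = [("chr1", 100, 500, "+"), ("chr1", 400, 900, "+"),
                 ("chr2", 100, 500, "+"), ("chr2", 400, 900, "+")]
        counts = [[100, 110, 10, 15], [15, 10, 100, 120],
                  [50, 55, 60, 52], [48, 60, 55, 50]]
        return make_matrix(juncs, counts,
                           groups={"s1": "control", "s2": "control",
                                   "s3": "knockdown", "s4": "knockdown"})

    def test_bh_correction_by_hand(self):
        # p = (0.01, 0.02, 0.9) -> BH q = (0.03, 0.03, 0.9)
        from statsmodels.stats.multitest import multipletests
        _, q, _, _ = multipletests([0.01, 0.02, 0.9], method="fdr_bh")
        assert list(np.round(q, 10)) == [0.03, 0.03, 0.9]

    def test_q_values_monotone_in_p(self):
        m = self._matrix_two_clusters()
        clusters = cluster_junctions(m, min_cluster_reads=10)
        _, tab = differential_splicing(m, clusters)
        tab = tab.sort_values("p_value")
        assert tab.q_value.is_monotonic_increasing
        assert (tab.q_value >= tab.p_value - 1e-12).all()

    def test_duplicate_cluster_ids_rejected(self):
        m = self._matrix_two_clusters()
        clusters = cluster_junctions(m, min_cluster_reads=10)
        clusters[1].cluster_id = clusters[0].cluster_id
        with pytest.raises(ValueError, match="duplicate"):
            differential_splicing(m, clusters)

    def test_flat_data_yields_no_significance(self):
        juncs = [("chr1", 100, 500, "+"), ("chr1", 400, 900, "+")]
        counts = [[100, 100, 100, 100], [100, 100, 100, 100]]
        m = make_matrix(juncs, counts,
                        groups={"s1": "control", "s2": "control",
                                "s3": "knockdown", "s4": "knockdown"})
        clusters = cluster_junctions(m, min_cluster_reads=10)
        _, tab = differential_splicing(m, clusters)
        assert not tab.significant.any()
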