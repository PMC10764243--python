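"""Effect estimation, k-means++ seeding, NB kernel, dispersions, and EM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mbcdeg.clustering import (
    em_fit,
    estimate_dispersions,
    estimate_gene_effects,
    kmeanspp_init,
    nb_log_pmf,
)
from mbcdeg.io_core import CountMatrix, GroupDesign
from mbcdeg.normalization import NormalizationFactors, cpm_factors
from mbcdeg.simulator import SimulationConfig, ideal_center, simulate_counts


def _unit_norm(n):
    return NormalizationFactors.from_factor("unit", np.ones(n))


class TestEstimateGeneEffects:
    def test_symmetric_gene_has_zero_effects(self, small_counts):
        matrix, design, norm = small_counts
        eff = estimate_gene_effects(matrix, design, norm)
        # gene g2: means 110 vs 100 are close; check exactly-equal means instead
        counts = np.array([[50, 50, 50, 50]])
        m = CountMatrix(["g"], ["a", "b", "c", "d"], counts)
        eff = estimate_gene_effects(m, design, _unit_norm(4))
        np.testing.assert_allclose(eff.beta_hat, 0.0, atol=1e-12)

    def test_four_fold_means_give_half_log4(self):
        # group means 400 vs 100 -> beta = (ln 2, -ln 2) up to the pseudo-count
        counts = np.array([[400, 400, 100, 100]])
        m = CountMatrix(["g"], ["a", "b", "c", "d"], counts)
        design = GroupDesign.from_labels(["X", "X", "Y", "Y"])
        eff = estimate_gene_effects(m, design, _unit_norm(4), pseudo=1e-9)
        np.testing.assert_allclose(eff.beta_hat[0], [0.6931, -0.6931], atol=1e-3)
        assert eff.baseline[0] == pytest.approx(0.5 * (np.log(400) + np.log(100)))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_rows_sum_to_zero(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(30, size=(20, 6))
        m = CountMatrix(
            [f"g{i}" for i in range(20)], [f"s{j}" for j in range(6)], counts
        )
        design = GroupDesign.from_labels(["X"] * 3 + ["Y"] * 3)
        norm = NormalizationFactors.from_factor("f", rng.uniform(0.5, 2.0, 6))
        eff = estimate_gene_effects(m, design, norm)
        assert np.abs(eff.beta_hat.sum(axis=1)).max() < 1e-10


class TestKmeansppInit:
    @staticmethod
    def _effects(beta):
        from mbcdeg.clustering import GeneEffects

        beta = np.asarray(beta, dtype=float)
        return GeneEffects(baseline=np.zeros(len(beta)), beta_hat=beta)

    def test_k_equals_g_exhausts_rows(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(8, 1))
        beta = np.hstack([raw, -raw])
        centers = kmeanspp_init(self._effects(beta), K=8, seed=1)
        got = set(map(tuple, np.round(centers, 12)))
        want = set(map(tuple, np.round(beta, 12)))
        assert got == want

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(50, 1))
        beta = np.hstack([raw, -raw])
        a = kmeanspp_init(self._effects(beta), K=3, seed=7)
        b = kmeanspp_init(self._effects(beta), K=3, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_k_exceeding_distinct_rows_rejected(self):
        beta = np.array([[1.0, -1.0]] * 5 + [[0.0, 0.0]] * 5)
        with pytest.raises(ValueError, match="distinct"):
            kmeanspp_init(self._effects(beta), K=3, seed=0)

    def test_separated_clouds_get_one_center_each(self):
        # three tight clouds; brute-force nearest-cloud assignment of the
        # chosen centers should cover all clouds in >= 95% of seeds
        rng = np.random.default_rng(42)
        anchors = np.array([[0.69, -0.69], [-1.1, 1.1], [0.0, 0.0]])
        raw = np.repeat(anchors, 60, axis=0) + rng.normal(0, 0.03, size=(180, 2))
        beta = raw - raw.mean(axis=1, keepdims=True)
        eff = self._effects(beta)
        hits = 0
        for seed in range(100):
            centers = kmeanspp_init(eff, K=3, seed=seed)
            nearest = np.argmin(
                ((centers[:, None, :] - anchors[None, :, :]) ** 2).sum(-1), axis=1
            )
            hits += len(set(nearest)) == 3
        assert hits >= 95


class TestNbLogPmf:
    def test_poisson_limit_closed_form(self):
        assert nb_log_pmf(0, 1.0, 0.0) == pytest.approx(-1.0)

    def test_hand_computed_nb_value(self):
        # y=2, mean=2, phi=0.5: r=2, p=0.5 -> P = C(3,2) * 0.5^4 = 0.1875
        assert nb_log_pmf(2, 2.0, 0.5) == pytest.approx(np.log(0.1875), abs=1e-4)

    @pytest.mark.parametrize("mean,disp", [(0.5, 0.0), (3.0, 0.2), (40.0, 1.5)])
    def test_matches_scipy(self, mean, disp):
        y = np.arange(0, 200)
        ours = nb_log_pmf(y, mean, disp)
        if disp == 0.0:
            ref = stats.poisson.logpmf(y, mean)
        else:
            r = 1.0 / disp
            ref = stats.nbinom.logpmf(y, r, r / (r + mean))
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    @pytest.mark.parametrize("mean,disp", [(1.0, 0.0), (5.0, 0.3), (20.0, 1.0)])
    def test_normalizes_to_one(self, mean, disp):
        y = np.arange(0, 5000)
        total = np.exp(nb_log_pmf(y, mean, disp)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)


class TestEstimateDispersions:
    def test_zero_variance_gene_gets_half_median(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(40, size=(50, 6))
        counts[0] = 25  # flat gene: zero within-group variance
        m = CountMatrix(
            [f"g{i}" for i in range(50)], [f"s{j}" for j in range(6)], counts
        )
        design = GroupDesign.from_labels(["X"] * 3 + ["Y"] * 3)
        phi = estimate_dispersions(m, design, _unit_norm(6))
        # raw MoM for the flat gene is clamped to 0, then shrunk halfway
        raw = np.zeros(50)
        x = counts.astype(float)
        for g in range(50):
            gm = np.array([x[g, :3].mean(), x[g, 3:].mean()])
            s2 = ((x[g] - np.repeat(gm, 3)) ** 2).sum() / 4
            raw[g] = max(0.0, (s2 - x[g].mean()) / x[g].mean() ** 2)
        assert phi[0] == pytest.approx(0.5 * np.median(raw))

    def test_underdispersion_clamped_to_zero_before_shrinkage(self):
        counts = np.array([[10, 10, 11, 10, 10, 11]] * 2)
        counts[1] = [5, 50, 500, 5, 50, 500]  # very overdispersed companion
        m = CountMatrix(["flat", "wild"], [f"s{j}" for j in range(6)], counts)
        design = GroupDesign.from_labels(["X"] * 3 + ["Y"] * 3)
        phi = estimate_dispersions(m, design, _unit_norm(6))
        assert phi[0] < phi[1]
        assert phi[0] >= 0

    def test_single_replicate_everywhere_rejected(self):
        counts = np.array([[3, 5], [2, 8]])
        m = CountMatrix(["g1", "g2"], ["a", "b"], counts)
        design = GroupDesign.from_labels(["X", "Y"])
        with pytest.raises(ValueError, match="unidentifiable"):
            estimate_dispersions(m, design, _unit_norm(2))

    def test_recovers_true_dispersion_in_simulation(self):
        rng = np.random.default_rng(11)
        g, n = 2000, 10
        mean = rng.uniform(50, 500, size=g)
        r = 1.0 / 0.2
        counts = rng.negative_binomial(
            r, r / (r + mean[:, None]), size=(g, 2 * n)
        )
        m = CountMatrix(
            [f"g{i}" for i in range(g)], [f"s{j}" for j in range(2 * n)], counts
        )
        design = GroupDesign.from_labels(["X"] * n + ["Y"] * n)
        phi = estimate_dispersions(m, design, _unit_norm(2 * n))
        assert 0.15 <= phi.mean() <= 0.25


class TestEmFit:
    def _fit(self, matrix, design, norm, K, seed=1, **kw):
        eff = estimate_gene_effects(matrix, design, norm)
        phi = estimate_dispersions(matrix, design, norm)
        init = kmeanspp_init(eff, K, seed)
        return em_fit(matrix, design, norm, K, init, phi, **kw)

    def test_single_component_on_null_data(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(60, size=(300, 6))
        m = CountMatrix(
            [f"g{i}" for i in range(300)], [f"s{j}" for j in range(6)], counts
        )
        design = GroupDesign.from_labels(["X"] * 3 + ["Y"] * 3)
        model = self._fit(m, design, _unit_norm(6), K=1)
        np.testing.assert_allclose(model.posteriors, 1.0)
        np.testing.assert_allclose(model.centers, 0.0, atol=0.05)

    def test_replica_recovers_ideal_centers(self, replica, replica_fit):
        # expected patterns: 4-fold up in A, 9-fold up in B, and flat
        ideal = np.array(
            [ideal_center(4, 1), ideal_center(9, 2), ideal_center(1, 1)]
        )
        centers = replica_fit.model.centers
        dist = np.abs(centers[:, None, :] - ideal[None, :, :]).max(-1)
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(dist)
        assert dist[rows, cols].max() <= 0.2

    def test_loglik_trace_monotone(self, replica_fit):
        model = replica_fit.model
        assert model.n_rescues == 0
        assert np.all(np.diff(model.loglik_trace) >= -1e-6)

    def test_posterior_rows_sum_to_one(self, replica_fit):
        post = replica_fit.model.posteriors
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-8)
        assert post.min() >= 0.0 and post.max() <= 1.0

    def test_center_rows_sum_to_zero(self, replica_fit):
        assert np.abs(replica_fit.model.centers.sum(axis=1)).max() < 1e-8

    def test_scale_invariance_joint_count_factor_rescaling(self):
        # the fit depends on (counts, factors) only through y_j / factor_j:
        # doubling one sample's counts together with its factor changes nothing
        config = SimulationConfig(n_genes=400, p_deg=0.2, p1=0.9, n=(3, 3), seed=9)
        matrix, _ = simulate_counts(config)
        design = config.design()
        norm = cpm_factors(matrix)
        base = self._fit(matrix, design, norm, K=3, seed=2)

        scaled_counts = matrix.counts.copy()
        scaled_counts[:, 0] *= 2
        scaled_factor = norm.factor.copy()
        scaled_factor[0] *= 2
        m2 = CountMatrix(matrix.gene_ids, matrix.sample_ids, scaled_counts)
        n2 = NormalizationFactors.from_factor("custom", scaled_factor)
        other = self._fit(m2, design, n2, K=3, seed=2)

        np.testing.assert_allclose(other.centers, base.centers, atol=1e-6)
        np.testing.assert_allclose(other.posteriors, base.posteriors, atol=1e-6)

    def test_label_swap_negates_centers_keeps_posteriors(self):
        # same samples, opposite group positions: centers negate (I=2),
        # posteriors (hence non-DEG posteriors) are unchanged
        config = SimulationConfig(n_genes=400, p_deg=0.2, p1=0.9, n=(3, 3), seed=10)
        matrix, _ = simulate_counts(config)
        norm = cpm_factors(matrix)
        d1 = GroupDesign.from_labels(["X"] * 3 + ["Y"] * 3)
        d2 = GroupDesign(
            group_names=["Y", "X"], group_index=np.array([1, 1, 1, 0, 0, 0])
        )
        a = self._fit(matrix, d1, norm, K=3, seed=4)
        b = self._fit(matrix, d2, norm, K=3, seed=4)
        np.testing.assert_allclose(b.centers, -a.centers, atol=1e-6)
        np.testing.assert_allclose(b.posteriors, a.posteriors, atol=1e-6)

    def test_gene_permutation_equivariance(self):
        config = SimulationConfig(n_genes=300, p_deg=0.2, p1=0.9, n=(3, 3), seed=12)
        matrix, _ = simulate_counts(config)
        design = config.design()
        norm = cpm_factors(matrix)
        eff = estimate_dispersions(matrix, design, norm)
        init = np.array([[0.7, -0.7], [-1.0, 1.0], [0.0, 0.0]])
        base = em_fit(matrix, design, norm, 3, init, eff)

        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.n_genes)
        m2 = CountMatrix(
            [matrix.gene_ids[i] for i in perm],
            matrix.sample_ids,
            matrix.counts[perm],
        )
        other = em_fit(m2, design, norm, 3, init, eff[perm])
        np.testing.assert_allclose(
            other.posteriors, base.posteriors[perm], atol=1e-6
        )

    def test_parameter_recovery_over_seeds(self):
        # two-group data, FC=4, P_DEG=0.2: the DEG-cluster centers should land
        # within 0.2 of (ln 2, -ln 2) (up to the library-imbalance offset)
        hits = 0
        for seed in range(20):
            config = SimulationConfig(
                n_genes=1000, p_deg=0.2, p1=0.5, n=(3, 3), seed=100 + seed
            )
            matrix, _ = simulate_counts(config)
            design = config.design()
            norm = cpm_factors(matrix)
            model = self._fit(matrix, design, norm, K=3, seed=seed)
            want = ideal_center(4, 1)
            err = np.abs(model.centers - want[None, :]).max(axis=1).min()
            err2 = np.abs(model.centers + want[None, :]).max(axis=1).min()
            hits += (err <= 0.2) and (err2 <= 0.2)
        assert hits >= 18

    def test_zero_count_genes_assigned_to_nondeg(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(50, size=(200, 6))
        counts[7] = 0
        m = CountMatrix(
            [f"g{i}" for i in range(200)], [f"s{j}" for j in range(6)], counts
        )
        design = GroupDesign.from_labels(["X"] * 3 + ["Y"] * 3)
        model = self._fit(m, design, _unit_norm(6), K=2, seed=1)
        k0 = int(np.argmin(np.linalg.norm(model.centers, axis=1)))
        assert model.posteriors[7, k0] == 1.0

    def test_bad_init_centers_rejected(self, small_counts):
        matrix, design, norm = small_counts
        phi = np.full(4, 0.1)
        with pytest.raises(ValueError, match="sum to zero"):
            em_fit(matrix, design, norm, 1, np.array([[0.5, 0.1]]), phi)
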