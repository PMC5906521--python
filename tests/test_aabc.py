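"""AABC machinery: kernel weights, Dirichlet resampling, rejection loop."""

import numpy as np
import pytest
from scipy import stats

from explantca import (
    DegenerateKernelError,
    PilotLibrary,
    PriorSpec,
    aabc_infer,
    build_pilot_library,
    epanechnikov_weights,
    pseudo_dataset,
    summaries_to_array,
)


def synthetic_library(m=40, n_rep=2, d=6, seed=0, prior=None):
    """A hand-made library: summaries are a smooth function of theta plus
    noise, so distances carry signal without any simulation."""
    prior = prior or PriorSpec()
    rng = np.random.default_rng(seed)
    thetas = prior.sample(rng, m)
    base = np.stack(
        [thetas[:, 1] / 40.0 + k for k in range(d)], axis=1
    )  # depends on c2 only
    summaries = base[:, None, :] + 0.1 * rng.standard_normal((m, n_rep, d))
    return PilotLibrary(thetas=thetas, summaries=summaries,
                        times_h=np.array([10.0, 20.0, 30.0]), prior=prior)


class TestEpanechnikovWeights:
    def test_zero_distance_gets_the_maximal_weight(self):
        lib = synthetic_library()
        k = 5
        w = epanechnikov_weights(lib.thetas[0], lib, k=k)
        scale = lib.prior.ranges
        d = np.linalg.norm((lib.thetas - lib.thetas[0]) / scale, axis=1)
        d_k1 = np.sort(d)[k]
        assert w[0] == pytest.approx(0.75 / d_k1)
        assert w[0] == w.max()

    def test_exactly_k_positive_weights(self):
        lib = synthetic_library()
        for k in (1, 5, 20):
            w = epanechnikov_weights([-30.0, 150.0, 0.5], lib, k=k)
            assert np.count_nonzero(w > 0) == k
            assert np.all(w >= 0)

    def test_beyond_kth_neighbour_weight_is_zero(self):
        lib = synthetic_library()
        k = 5
        w = epanechnikov_weights([-30.0, 150.0, 0.5], lib, k=k)
        scale = lib.prior.ranges
        d = np.linalg.norm((lib.thetas - np.array([-30.0, 150.0, 0.5])) / scale, axis=1)
        far = np.argsort(d)[k:]
        assert np.all(w[far] == 0.0)

    def test_equidistant_tie_broken_by_index(self):
        prior = PriorSpec(c1=(-40, -20), c2=(40, 280), p_move=(0, 1))
        lib = PilotLibrary(
            thetas=np.array([[-25.0, 100.0, 0.5], [-35.0, 100.0, 0.5]]),
            summaries=np.zeros((2, 2, 6)),
            times_h=np.array([10.0, 20.0, 30.0]),
            prior=prior,
        )
        w = epanechnikov_weights([-30.0, 100.0, 0.5], lib, k=1)
        assert np.count_nonzero(w > 0) == 1
        assert w[0] > 0.0

    def test_duplicated_theta_star_is_degenerate(self):
        lib = synthetic_library()
        thetas = lib.thetas.copy()
        thetas[:3] = thetas[0]
        dup = PilotLibrary(thetas=thetas, summaries=lib.summaries,
                           times_h=lib.times_h, prior=lib.prior)
        with pytest.raises(DegenerateKernelError):
            epanechnikov_weights(thetas[0], dup, k=2)

    def test_k_bounds_validated(self):
        lib = synthetic_library(m=10)
        with pytest.raises(ValueError):
            epanechnikov_weights(lib.thetas[0], lib, k=10)


class TestPseudoDataset:
    def test_single_positive_weight_is_a_point_mass(self):
        lib = synthetic_library()
        w = np.zeros(lib.m)
        w[7] = 1.3
        rng = np.random.default_rng(0)
        x = pseudo_dataset(lib, w, n_replicates=6, rng=rng)
        for row in x:
            assert any(np.array_equal(row, rep) for rep in lib.summaries[7])

    def test_resampled_rows_are_library_members(self):
        lib = synthetic_library()
        w = epanechnikov_weights([-30.0, 150.0, 0.5], lib, k=8)
        rng = np.random.default_rng(1)
        x = pseudo_dataset(lib, w, n_replicates=10, rng=rng)
        flat = lib.summaries.reshape(-1, lib.summaries.shape[2])
        for row in x:
            assert any(np.array_equal(row, member) for member in flat)

    def test_concentrated_weights_dominate_resampling(self):
        """omega = (large, tiny): the resampling frequency of particle 0
        over 10,000 draws matches its phi within binomial noise."""
        lib = synthetic_library(m=2)
        w = np.array([50.0, 1e-8])
        rng = np.random.default_rng(2)
        x = pseudo_dataset(lib, w, n_replicates=10_000, rng=rng)
        from0 = np.mean([
            any(np.array_equal(row, rep) for rep in lib.summaries[0]) for row in x
        ])
        assert from0 >= 1.0 - 2 * np.sqrt(0.01 * 0.99 / 10_000) - 1e-3

    def test_all_zero_weights_rejected(self):
        lib = synthetic_library()
        with pytest.raises(ValueError):
            pseudo_dataset(lib, np.zeros(lib.m), 2, np.random.default_rng(0))


class TestInference:
    def test_exact_acceptance_count_at_five_percent(self):
        lib = synthetic_library(m=60)
        observed = lib.summaries[3]
        post = aabc_infer(observed, lib.prior, lib, n_proposals=1000, k=10,
                          accept_quantile=0.05, seed=0)
        assert post.n_accepted == 50
        assert post.acceptance_fraction == pytest.approx(0.05)
        assert np.all(post.distances < post.epsilon)

    def test_epsilon_infinite_recovers_the_prior(self):
        lib = synthetic_library(m=60)
        observed = lib.summaries[3]
        post = aabc_infer(observed, lib.prior, lib, n_proposals=2000, k=10,
                          accept_quantile=1.0, seed=1)
        assert post.n_accepted == 2000
        b = lib.prior.bounds
        for i in range(3):
            p = stats.kstest(
                post.thetas[:, i], stats.uniform(b[i, 0], b[i, 1] - b[i, 0]).cdf
            ).pvalue
            assert p > 0.01

    def test_posterior_support_within_prior(self):
        lib = synthetic_library(m=60)
        post = aabc_infer(lib.summaries[5], lib.prior, lib, n_proposals=500,
                          k=10, accept_quantile=0.1, seed=2)
        assert all(lib.prior.contains(t) for t in post.thetas)

    def test_informative_summaries_concentrate_the_posterior(self):
        """Summaries depend on c2 only: the accepted c2 values must hug the
        pseudo-truth far more tightly than the prior does."""
        lib = synthetic_library(m=200, seed=3)
        truth_c2 = 90.0
        observed = np.stack([truth_c2 / 40.0 + np.arange(6.0)] * 2)
        post = aabc_infer(observed, lib.prior, lib, n_proposals=2000, k=5,
                          accept_quantile=0.05, seed=3)
        assert np.std(post.thetas[:, 1]) < 0.4 * np.std(lib.prior.sample(np.random.default_rng(0), 2000)[:, 1])
        assert abs(np.mean(post.thetas[:, 1]) - truth_c2) < 30.0

    def test_dimension_mismatch_rejected(self):
        lib = synthetic_library()
        with pytest.raises(ValueError):
            aabc_infer(np.ones((2, 4)), lib.prior, lib, n_proposals=10, k=3,
                       accept_quantile=0.5, seed=0)


class TestPilotLibrary:
    def test_shape_contract_and_determinism(self, tiny_library, small_params, small_mask):
        assert tiny_library.thetas.shape == (30, 3)
        assert tiny_library.summaries.shape == (30, 2, 6)
        rebuilt = build_pilot_library(
            PriorSpec(), m=3, n_replicates=2, sim_config=small_params,
            initial_mask=small_mask, seed=7,
        )
        again = build_pilot_library(
            PriorSpec(), m=3, n_replicates=2, sim_config=small_params,
            initial_mask=small_mask, seed=7,
        )
        np.testing.assert_array_equal(rebuilt.thetas, again.thetas)
        np.testing.assert_array_equal(rebuilt.summaries, again.summaries)

    def test_collapsed_prior_gives_identical_thetas(self, small_params, small_mask):
        prior = PriorSpec(c1=(-25.0, -24.999999), c2=(120.0, 120.000001),
                          p_move=(0.2, 0.2000001))
        lib = build_pilot_library(prior, m=3, n_replicates=1,
                                  sim_config=small_params,
                                  initial_mask=small_mask, seed=9)
        assert np.all(np.ptp(lib.thetas, axis=0) <= np.array([1e-6, 1e-6, 1e-7]))

    def test_summaries_to_array_shapes(self, tiny_library):
        arr = summaries_to_array(tiny_library.summaries[0])
        assert arr.shape == (2, 6)
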