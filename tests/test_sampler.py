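import numpy as np
import pytest

from tractrisk.model_core import ModelData, ModelSpec
from tractrisk.sampler import _Blocks, load_samples, run_chain, save_samples
from tractrisk.synthetic import simulate_geography
from tractrisk.tract_io import AdjacencyGraph


def _dummy_data(n=4, C=3, graph=None):
    return ModelData(y=np.zeros(n), E=np.ones(n), q=np.zeros((n, C)), graph=graph)


def _prior_spec(**over):
    base = dict(variant=1, n_covariates=3, prior_only=True,
                iterations=20000, burn_in=2000, seed=2)
    base.update(over)
    return ModelSpec(**base)


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_fit):
        data, samples = small_fit
        again = run_chain(data, samples.spec)
        assert (again.beta1 == samples.beta1).all()
        assert (again.w == samples.w).all()
        assert (again.theta == samples.theta).all()
        assert (again.deviance == samples.deviance).all()

    def test_different_seed_differs(self, small_fit):
        data, samples = small_fit
        spec2 = ModelSpec.from_dict({**samples.spec.to_dict(), "seed": 99})
        other = run_chain(data, spec2)
        assert not (other.beta1 == samples.beta1).all()


class TestPriorRecovery:
    def test_flat_dirichlet_weights(self):
        s = run_chain(_dummy_data(), _prior_spec(iterations=30000))
        assert np.allclose(s.w.sum(axis=1), 1.0, atol=1e-12)
        assert s.w.mean(axis=0) == pytest.approx([1 / 3] * 3, abs=0.02)

    def test_asymmetric_dirichlet_component_mean(self):
        s = run_chain(_dummy_data(),
                      _prior_spec(dirichlet_alpha=[10, 1, 1], iterations=30000))
        assert s.w.mean(axis=0)[0] == pytest.approx(10 / 12, abs=0.02)

    def test_uniform_scale_prior_mean(self):
        # marginally sigma_1 ~ Uniform(0, 100): mean 50
        s = run_chain(_dummy_data(), _prior_spec(iterations=60000, burn_in=5000,
                                                 seed=4))
        assert s.sigma1.mean() == pytest.approx(50, abs=5)
        assert 0 < s.sigma1.min() and s.sigma1.max() < 100

    def test_beta_mixing_moments(self, grid3):
        _, g = grid3
        spec = _prior_spec(variant=4, n_covariates=2, fixed_sigma_u=1.0,
                           fixed_sigma_v=1.0, store_mixing_trace=True,
                           iterations=15000, seed=3)
        s = run_chain(_dummy_data(n=9, C=2, graph=g), spec)
        a = s.a_trace.astype(float).ravel()
        assert a.mean() == pytest.approx(0.5, abs=0.02)
        assert a.var() == pytest.approx(1 / 12, abs=0.01)
        assert ((s.a_trace > 0) & (s.a_trace < 1)).all()

    def test_beta1_normal_prior_recovery(self):
        # with the likelihood disabled and sigma_1 fixed, beta1 draws
        # must match their Normal prior's moments
        spec = _prior_spec(fixed_sigma1=2.0, beta1_prior_mean=1.0,
                           iterations=40000, seed=5)
        s = run_chain(_dummy_data(), spec)
        assert s.beta1.mean() == pytest.approx(1.0, abs=0.1)
        assert s.beta1.std() == pytest.approx(2.0, abs=0.1)

    def test_u_pinned_when_prior_precision_huge(self):
        spec = _prior_spec(fixed_sigma_u=1e-8, iterations=2000, burn_in=500)
        s = run_chain(_dummy_data(), spec)
        assert np.abs(s.u_mean).max() < 1e-6


class TestIcarUpdates:
    def test_path_graph_difference_variances(self):
        # constrained ICAR on a 3-path: covariance is the Laplacian
        # pseudo-inverse; prior-only log(theta) equals v exactly
        path = AdjacencyGraph(ids=["a", "b", "c"], neighbors=[[1], [0, 2], [1]])
        spec = ModelSpec(variant=2, n_covariates=2, prior_only=True,
                         fixed_sigma_v=1.0, iterations=40000, burn_in=2000,
                         seed=6)
        s = run_chain(_dummy_data(n=3, C=2, graph=path), spec)
        v = np.log(s.theta.astype(float))
        v -= v.mean(axis=1, keepdims=True)
        L = np.diag([1.0, 2.0, 1.0]) - path.sparse_matrix().toarray()
        Lp = np.linalg.pinv(L)
        for a, b in [(0, 1), (1, 2), (0, 2)]:
            assert np.var(v[:, a] - v[:, b]) == pytest.approx(
                Lp[a, a] + Lp[b, b] - 2 * Lp[a, b], rel=0.1)

    def test_recentring_keeps_sum_zero(self, grid3):
        _, g = grid3
        rng = np.random.default_rng(11)
        data = ModelData(y=rng.poisson(3.0, 9), E=np.full(9, 3.0),
                         q=rng.integers(0, 10, (9, 2)).astype(float), graph=g)
        spec = ModelSpec(variant=3, n_covariates=2, iterations=200, burn_in=100,
                         seed=12)
        blocks = _Blocks(data, spec, np.random.default_rng(12))
        for _ in range(50):
            blocks.sweep()
            assert blocks.state.v.sum() == pytest.approx(0.0, abs=1e-10)

    def test_island_spatial_effect_fixed_at_zero(self):
        with pytest.warns(UserWarning, match="island"):
            g = AdjacencyGraph(ids=["a", "b", "c"],
                               neighbors=[[1], [0], []])
        spec = ModelSpec(variant=2, n_covariates=2, iterations=500, burn_in=100,
                         seed=13)
        rng = np.random.default_rng(0)
        data = ModelData(y=rng.poisson(2.0, 3), E=np.full(3, 2.0),
                         q=np.zeros((3, 2)), graph=g)
        s = run_chain(data, spec)
        assert s.v_mean[2] == 0.0


class TestDegenerateGuards:
    def test_zero_proposal_scale_never_moves(self):
        data = _dummy_data()
        spec = ModelSpec(variant=1, n_covariates=3, iterations=50, burn_in=10,
                         seed=1)
        blocks = _Blocks(data, spec, np.random.default_rng(1))
        blocks.log_scales = {k: (np.full_like(v, -np.inf)
                                 if isinstance(v, np.ndarray) else -np.inf)
                             for k, v in blocks.log_scales.items()}
        b0, b1 = blocks.state.beta0, blocks.state.beta1
        w = blocks.state.w.copy()
        for _ in range(20):
            blocks.sweep()
        assert blocks.state.beta0 == b0 and blocks.state.beta1 == b1
        assert (blocks.state.w == w).all()

    def test_zero_expected_count_rejected(self):
        data = ModelData(y=np.zeros(3), E=np.array([1.0, 0.0, 1.0]),
                         q=np.zeros((3, 2)))
        with pytest.raises(ValueError, match="E_i > 0"):
            run_chain(data, ModelSpec(variant=1, n_covariates=2,
                                      iterations=100, burn_in=10))

    def test_scale_draws_stay_inside_bounds(self, small_fit):
        _, samples = small_fit
        for tr in (samples.sigma_u, samples.sigma1):
            assert 0 < tr.min() and tr.max() < samples.spec.sigma_bound


class TestAdaptation:
    def test_acceptance_rates_reasonable_after_adaptation(self, small_fit):
        _, samples = small_fit
        for name, rate in samples.acceptance.items():
            assert 0.15 < rate < 0.75, (name, rate)


class TestArchive:
    def test_save_load_roundtrip(self, small_fit, tmp_path):
        _, samples = small_fit
        p = tmp_path / "run.npz"
        save_samples(samples, p)
        back = load_samples(p)
        assert (back.beta1 == samples.beta1).all()
        assert (back.theta == samples.theta).all()
        assert back.spec.to_dict() == samples.spec.to_dict()
        assert back.acceptance == pytest.approx(samples.acceptance)
        assert back.m == samples.m
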