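"""Closed-form update contracts for the individual-level model."""

import numpy as np
import pytest

from cafeh.data import GenotypePanel, Hyperparameters, TraitMatrix
from cafeh.infer import FitConfig, fit_g, initialize
from cafeh.model_g import (
    compute_elbo,
    expected_residual,
    suffstats_from_individual,
    update_alpha,
    update_s,
    update_tau,
    update_w,
)


def _setup(x, y, K=1, p0=0.1, **hkw):
    panel = GenotypePanel(np.asarray(x, float), [f"s{i}" for i in range(np.shape(x)[1])],
                          standardized=True)
    traits = TraitMatrix(np.asarray(y, float), [f"t{j}" for j in range(np.shape(y)[1])])
    hyper = Hyperparameters.default(K, panel.n_variants, p0=p0, **hkw)
    stats = suffstats_from_individual(panel, traits)
    post = initialize(stats, hyper, FitConfig(K=K))
    return panel, traits, hyper, post


def _std(rng, n, g):
    x = rng.standard_normal((n, g))
    return (x - x.mean(axis=0)) / x.std(axis=0)


class TestExpectedResidual:
    def test_single_component_excludes_itself(self):
        rng = np.random.default_rng(0)
        x = _std(rng, 20, 3)
        y = rng.standard_normal((20, 1))
        panel, traits, hyper, post = _setup(x, y)
        np.testing.assert_allclose(
            expected_residual(0, 0, post, panel, traits), y[:, 0]
        )

    def test_inactive_components_leave_trait_untouched(self):
        rng = np.random.default_rng(1)
        x = _std(rng, 20, 3)
        y = rng.standard_normal((20, 2))
        panel, traits, hyper, post = _setup(x, y, K=3)
        post.w_mean[:] = rng.standard_normal(post.w_mean.shape)
        post.s_prob[:] = 0.0
        np.testing.assert_allclose(
            expected_residual(1, 0, post, panel, traits), y[:, 1]
        )

    def test_subtracts_other_components_posterior_mean(self):
        rng = np.random.default_rng(2)
        x = _std(rng, 5, 2)
        y = rng.standard_normal((5, 1))
        panel, traits, hyper, post = _setup(x, y, K=2)
        b, g, sp = 0.7, 1, 0.6
        post.phi[1] = np.array([0.0, 1.0])
        post.s_prob[0, 1] = sp
        post.w_mean[0, 1, g] = b
        expected = y[:, 0] - x[:, g] * b * sp
        np.testing.assert_allclose(
            expected_residual(0, 0, post, panel, traits), expected
        )

    def test_out_of_range_indices_raise(self):
        rng = np.random.default_rng(3)
        panel, traits, hyper, post = _setup(_std(rng, 10, 2),
                                            rng.standard_normal((10, 1)))
        with pytest.raises(IndexError):
            expected_residual(1, 0, post, panel, traits)
        with pytest.raises(IndexError):
            expected_residual(0, 5, post, panel, traits)


class TestUpdateW:
    def test_orthogonal_residual_gives_zero_mean(self):
        x = np.array([[1.0, 0.0]] * 2 + [[-1.0, 0.0]] * 2)
        x[:, 1] = [1, -1, 1, -1]
        y = x[:, 1:2].copy()  # orthogonal to column 0
        panel, traits, hyper, post = _setup(x, y)
        mean, var = update_w(0, 0, post, panel, traits, hyper)
        assert abs(mean[0]) < 1e-12

    def test_strong_prior_shrinks_to_spike(self):
        rng = np.random.default_rng(4)
        x = _std(rng, 30, 2)
        y = (0.5 * x[:, :1]) + 0.1 * rng.standard_normal((30, 1))
        panel, traits, hyper, post = _setup(x, y, fixed_alpha=1e12, fixed_tau=1.0)
        mean, var = update_w(0, 0, post, panel, traits, hyper)
        assert np.all(np.abs(mean) < 1e-6)
        assert np.all(var < 1e-6)

    def test_closed_form_posterior_mean_on_constructed_toy(self):
        # N=50, r = 0.3 x_g + small noise, E[tau]=1, E[alpha]=10:
        # mean ~= 0.3 * 50 / (50 + 10) = 0.25
        rng = np.random.default_rng(5)
        x = _std(rng, 50, 1)
        y = 0.3 * x + 0.05 * rng.standard_normal((50, 1))
        panel, traits, hyper, post = _setup(x, y, fixed_alpha=10.0, fixed_tau=1.0)
        mean, var = update_w(0, 0, post, panel, traits, hyper)
        assert mean[0] == pytest.approx(0.25, abs=0.02)
        assert var[0] == pytest.approx(1.0 / 60.0, rel=1e-6)


class TestUpdateS:
    def test_zero_prior_excludes_activity(self):
        rng = np.random.default_rng(6)
        x = _std(rng, 50, 3)
        y = x[:, :1] + 0.1 * rng.standard_normal((50, 1))
        panel, traits, hyper, post = _setup(x, y, p0=0.0)
        update_w(0, 0, post, panel, traits, hyper)
        assert update_s(0, 0, post, hyper, panel, traits) == 0.0

    def test_pure_noise_stays_below_half(self):
        rng = np.random.default_rng(7)
        x = _std(rng, 500, 20)
        y = rng.standard_normal((500, 1))
        panel, traits, hyper, post = _setup(x, y, p0=0.1)
        post = fit_g(panel, traits, hyper=hyper,
                     config=FitConfig(K=1, standardize=False))
        assert post.s_prob[0, 0] < 0.5

    def test_strong_signal_activates(self):
        rng = np.random.default_rng(8)
        x = _std(rng, 500, 20)
        b = np.zeros((20, 1))
        b[3] = 0.5  # rho = 0.2
        y = x @ b + rng.standard_normal((500, 1))
        panel, traits, hyper, post = _setup(x, y, p0=0.1)
        post = fit_g(panel, traits, hyper=hyper,
                     config=FitConfig(K=1, standardize=False))
        assert post.s_prob[0, 0] > 0.95


class TestUpdatePhi:
    def test_no_data_term_returns_prior(self):
        rng = np.random.default_rng(9)
        x = _std(rng, 40, 4)
        y = rng.standard_normal((40, 2))
        panel, traits, hyper, post = _setup(x, y, K=1)
        from cafeh.model_g import update_phi, update_w

        for t in range(2):
            update_w(t, 0, post, panel, traits, hyper)
        post.s_prob[:] = 0.0
        row = update_phi(0, post, hyper, panel, traits)
        np.testing.assert_allclose(row, hyper.pi0, atol=1e-12)

    def test_perfect_ld_duplicates_split_mass(self):
        rng = np.random.default_rng(10)
        x = _std(rng, 200, 3)
        x[:, 1] = x[:, 0]  # exact duplicate
        y = 0.6 * x[:, :1] + rng.standard_normal((200, 1))
        panel, traits, hyper, post = _setup(x, y)
        post = fit_g(panel, traits, hyper=hyper,
                     config=FitConfig(K=1, standardize=False))
        assert post.phi[0, 0] == pytest.approx(0.5, abs=0.02)
        assert post.phi[0, 1] == pytest.approx(0.5, abs=0.02)

    def test_joint_fit_concentrates_more_than_single_trait(self):
        # four traits sharing one causal variant: the shared phi should put
        # more mass on it than a fit of any single trait alone
        rng = np.random.default_rng(11)
        n, g = 500, 50
        x = _std(rng, n, g)
        x[:, 1] = 0.9 * x[:, 0] + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        causal = 0
        y = np.empty((n, 4))
        for t in range(4):
            genetic = 0.45 * x[:, causal]
            y[:, t] = genetic + rng.standard_normal(n)
        panel = GenotypePanel(x, [f"s{i}" for i in range(g)], standardized=True)
        joint = fit_g(panel, TraitMatrix(y, list("abcd")),
                      config=FitConfig(K=1, standardize=False))
        single = fit_g(panel, TraitMatrix(y[:, :1], ["a"]),
                       config=FitConfig(K=1, standardize=False))
        assert joint.phi[0, causal] > single.phi[0, causal]


class TestUpdateAlpha:
    def test_fixed_point_idempotence(self, two_group):
        panel, traits, truth, post = two_group
        hyper = Hyperparameters.default(post.K, post.G)
        p = post.copy()
        first = update_alpha(0, 0, p, hyper)
        second = update_alpha(0, 0, p, hyper)
        assert first == second

    def test_gamma_posterior_mean_with_active_component(self):
        # fully active component with E[w^2]=0.2, a0=b0=1e-6:
        # E[alpha] = (a0 + 1/2) / (b0 + 0.1) ~= 5
        rng = np.random.default_rng(12)
        x = _std(rng, 30, 2)
        y = rng.standard_normal((30, 1))
        panel, traits, hyper, post = _setup(x, y)
        post.s_prob[0, 0] = 1.0
        post.phi[0] = np.array([1.0, 0.0])
        post.w_mean[0, 0] = np.array([np.sqrt(0.15), 0.0])
        post.w_var[0, 0] = np.array([0.05, 0.05])
        shape, rate = update_alpha(0, 0, post, hyper)
        assert shape / rate == pytest.approx(5.0, rel=1e-3)

    def test_inactive_component_reverts_to_prior(self):
        rng = np.random.default_rng(13)
        x = _std(rng, 30, 2)
        y = rng.standard_normal((30, 1))
        panel, traits, hyper, post = _setup(x, y)
        post.s_prob[0, 0] = 0.0
        post.w_mean[0, 0] = np.array([3.0, 3.0])
        shape, rate = update_alpha(0, 0, post, hyper)
        assert shape == pytest.approx(hyper.a0)
        assert rate == pytest.approx(hyper.b0)


class TestUpdateTau:
    def test_null_model_posterior_mean_near_one(self):
        rng = np.random.default_rng(14)
        x = _std(rng, 100, 5)
        y = rng.standard_normal((100, 1))
        y = (y - y.mean()) / y.std()
        panel, traits, hyper, post = _setup(x, y)
        post.s_prob[:] = 0.0
        shape, rate = update_tau(0, post, panel, traits, hyper)
        assert shape / rate == pytest.approx(1.0, rel=1e-6)

    def test_zero_residual_limit_gives_large_precision(self):
        rng = np.random.default_rng(15)
        x = _std(rng, 100, 2)
        y = x[:, :1] * 2.0
        panel = GenotypePanel(x, ["a", "b"], standardized=True)
        traits = TraitMatrix(y, ["t"])
        hyper = Hyperparameters.default(1, 2)
        post = fit_g(panel, traits, hyper=hyper,
                     config=FitConfig(K=1, standardize=False))
        assert post.tau_shape[0] / post.tau_rate[0] > 1e3

    def test_added_terms_scale_linearly_with_n(self):
        rng = np.random.default_rng(16)
        x = _std(rng, 50, 2)
        y = rng.standard_normal((50, 1))
        x2, y2 = np.vstack([x, x]), np.vstack([y, y])
        p1 = _setup(x, y)
        p2 = _setup(x2, y2)
        for args in (p1, p2):
            args[3].s_prob[:] = 0.0
        s1, r1 = update_tau(0, p1[3], p1[0], p1[1], p1[2])
        s2, r2 = update_tau(0, p2[3], p2[0], p2[1], p2[2])
        h = p1[2]
        assert s2 - h.c0 == pytest.approx(2 * (s1 - h.c0))
        assert r2 - h.d0 == pytest.approx(2 * (r1 - h.d0), rel=1e-9)


class TestElbo:
    def test_repeated_call_is_pure(self, two_group):
        panel, traits, truth, post = two_group
        hyper = Hyperparameters.default(post.K, post.G)
        from cafeh.data import standardize_genotypes

        sp = standardize_genotypes(panel)
        st = traits.standardized()
        assert compute_elbo(post, hyper, sp, st) == compute_elbo(post, hyper, sp, st)

    def test_full_sweep_increases_elbo_on_signal(self, two_group):
        panel, traits, truth, post = two_group
        trace = post.elbo_trace
        assert trace[1] > trace[0]

    def test_trace_non_decreasing(self, two_group):
        _, _, _, post = two_group
        assert np.all(np.diff(post.elbo_trace) >= -1e-6)


class TestEquivariance:
    def test_trait_permutation_permutes_outputs(self):
        rng = np.random.default_rng(17)
        x = _std(rng, 300, 30)
        b = np.zeros(30)
        b[4] = 0.5
        y = np.stack([x @ b + rng.standard_normal(300),
                      rng.standard_normal(300)], axis=1)
        panel = GenotypePanel(x, [f"s{i}" for i in range(30)], standardized=True)
        perm = [1, 0]
        f1 = fit_g(panel, TraitMatrix(y, ["a", "b"]),
                   config=FitConfig(K=3, standardize=False))
        f2 = fit_g(panel, TraitMatrix(y[:, perm], ["b", "a"]),
                   config=FitConfig(K=3, standardize=False))
        np.testing.assert_allclose(f1.s_prob[perm], f2.s_prob, atol=1e-10)
        np.testing.assert_allclose(f1.w_mean[perm], f2.w_mean, atol=1e-10)
        np.testing.assert_allclose(f1.phi, f2.phi, atol=1e-10)
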