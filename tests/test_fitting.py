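import numpy as np
import pytest
from dataclasses import replace
from scipy import optimize

from poprf import (
    Dataset,
    ModelConfig,
    fit_hsm,
    fit_multi_restart,
    fit_per_neuron,
    hsm_forward,
    loglik_gradient,
    pack_params,
    poisson_loglik,
    random_init,
    unpack_params,
)
from poprf.model_core import CorticalLayer, HSMParams


def small_problem(rng, s1=2, s2=2, s3=3, n=20, p=8):
    cfg = ModelConfig(s3=s3, s1=s1, s2=s2, p=p)
    params = random_init(cfg, rng)
    images = rng.standard_normal((n, p, p))
    y = rng.poisson(1.5, size=(n, s3)).astype(float)
    return cfg, params, Dataset(images=images, train_responses=y)


class TestPoissonLoglik:
    def test_zero_responses_leave_only_rate_term(self, rng):
        cfg, params, data = small_problem(rng)
        data0 = Dataset(images=data.images,
                        train_responses=np.zeros_like(data.train_responses))
        rates = hsm_forward(params, data.images)
        assert poisson_loglik(params, data0) == pytest.approx(-rates.sum())

    def test_poisson_term_maximized_at_rate_equal_response(self):
        # y log M - M as a function of the rate peaks at M = y
        y = 3.7
        ms = np.linspace(0.5, 10, 2000)
        vals = y * np.log(ms) - ms
        assert ms[np.argmax(vals)] == pytest.approx(y, abs=0.01)

    def test_matches_naive_double_loop(self, rng):
        cfg, params, data = small_problem(rng)
        rates = hsm_forward(params, data.images)
        expected = 0.0
        for i in range(rates.shape[0]):
            for j in range(rates.shape[1]):
                expected += (data.train_responses[i, j] * np.log(rates[i, j])
                             - rates[i, j])
        assert poisson_loglik(params, data) == pytest.approx(expected, rel=1e-12)

    def test_negative_responses_rejected(self, rng):
        cfg, params, data = small_problem(rng)
        with pytest.raises(ValueError):
            Dataset(images=data.images,
                    train_responses=data.train_responses - 10.0)


class TestGradient:
    def test_matches_central_finite_differences(self, rng):
        cfg, params, data = small_problem(rng)
        grad = loglik_gradient(params, data)
        x0 = pack_params(params)
        h = 1e-5
        fd = np.empty_like(x0)
        for i in range(x0.size):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += h
            xm[i] -= h
            fd[i] = (poisson_loglik(unpack_params(xp, cfg), data)
                     - poisson_loglik(unpack_params(xm, cfg), data)) / (2 * h)
        scale = np.maximum(np.abs(fd), np.abs(grad).max() * 1e-4)
        assert np.max(np.abs(grad - fd) / scale) < 1e-4

    def test_zero_at_one_parameter_optimum(self, rng):
        # freeze everything but one output threshold and locate its optimum
        cfg, params, data = small_problem(rng, s3=1, s2=1, s1=1)
        x0 = pack_params(params)
        t_idx = x0.size - 1

        def neg_ll(t):
            x = x0.copy()
            x[t_idx] = t
            return -poisson_loglik(unpack_params(x, cfg), data)

        res = optimize.minimize_scalar(neg_ll, bounds=(-10, 10),
                                       method="bounded",
                                       options={"xatol": 1e-12})
        x_opt = x0.copy()
        x_opt[t_idx] = res.x
        grad = loglik_gradient(unpack_params(x_opt, cfg), data)
        assert abs(grad[t_idx]) < 1e-5

    def test_equivariant_under_hidden_permutation(self, rng):
        cfg, params, data = small_problem(rng, s2=3)
        perm = np.array([2, 0, 1])
        permuted = HSMParams(
            lgn=params.lgn,
            hidden=CorticalLayer(params.hidden.weights[perm],
                                 params.hidden.thresholds[perm]),
            output=CorticalLayer(params.output.weights[:, perm],
                                 params.output.thresholds))
        g = loglik_gradient(params, data)
        gp = loglik_gradient(permuted, data)
        s1, s2, s3 = 2, 3, 3
        off = 6 * s1
        wh = g[off:off + s2 * s1].reshape(s2, s1)
        whp = gp[off:off + s2 * s1].reshape(s2, s1)
        assert np.allclose(whp, wh[perm])
        th = g[off + s2 * s1:off + s2 * s1 + s2]
        thp = gp[off + s2 * s1:off + s2 * s1 + s2]
        assert np.allclose(thp, th[perm])


class TestRandomInit:
    def test_draws_respect_bounds(self):
        cfg = ModelConfig(s3=4, s1=3, p=15)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            params = random_init(cfg, rng)
            for d in params.lgn:
                assert 0 <= d.mu_x <= 14 and 0 <= d.mu_y <= 14
                assert 0 < d.sigma_c <= 15 and 0 < d.sigma_s <= 15

    def test_deterministic_given_seed(self):
        cfg = ModelConfig(s3=4, s1=3, p=15)
        a = random_init(cfg, np.random.default_rng(42))
        b = random_init(cfg, np.random.default_rng(42))
        assert np.array_equal(pack_params(a), pack_params(b))


class TestFitHsm:
    def test_ascent_contract_and_bounds(self, rng):
        cfg, params, data = small_problem(rng, n=60)
        cfg = replace(cfg, maxfun=300)
        result = fit_hsm(data, cfg, params)
        assert result.final_loglik >= poisson_loglik(params, data) - 1e-9
        assert result.final_loglik >= result.initial_loglik - 1e-9
        for d in result.params.lgn:
            assert 0 <= d.mu_x <= cfg.p - 1 and 0 <= d.mu_y <= cfg.p - 1
            assert 0 < d.sigma_c <= cfg.p and 0 < d.sigma_s <= cfg.p

    def test_deterministic_given_init(self, rng):
        cfg, params, data = small_problem(rng, n=40)
        cfg = replace(cfg, maxfun=150)
        a = fit_hsm(data, cfg, params)
        b = fit_hsm(data, cfg, params)
        assert np.array_equal(pack_params(a.params), pack_params(b.params))

    def test_objective_invariant_to_stimulus_ordering(self, rng):
        # the objective is a batch sum: permuting stimuli together with
        # their responses leaves the log-likelihood and gradient unchanged
        cfg, params, data = small_problem(rng, n=40)
        perm = rng.permutation(40)
        data_perm = Dataset(images=data.images[perm],
                            train_responses=data.train_responses[perm])
        assert poisson_loglik(params, data) == pytest.approx(
            poisson_loglik(params, data_perm), rel=1e-12)
        assert np.allclose(loglik_gradient(params, data),
                           loglik_gradient(params, data_perm))


@pytest.fixture(scope="module")
def restart_problem():
    rng = np.random.default_rng(5)
    cfg, _, data = small_problem(rng, n=60)
    return replace(cfg, maxfun=150), data


class TestMultiRestart:
    def test_best_on_training_selected_and_recorded(self, restart_problem):
        cfg, data = restart_problem
        result = fit_multi_restart(data, replace(cfg, n_restarts=4, rng_seed=1))
        assert len(result.restarts) == 4
        assert result.train_performance == max(
            s["train_performance"] for s in result.restarts)

    def test_best_of_k_monotone_in_k(self, restart_problem):
        cfg, data = restart_problem
        perfs = [fit_multi_restart(
            data, replace(cfg, n_restarts=k, rng_seed=1)).train_performance
            for k in (1, 2, 4)]
        assert perfs[0] <= perfs[1] <= perfs[2]

    def test_bitwise_reproducible_from_master_seed(self, restart_problem):
        cfg, data = restart_problem
        cfg = replace(cfg, n_restarts=3, rng_seed=9)
        a = fit_multi_restart(data, cfg)
        b = fit_multi_restart(data, cfg)
        assert np.array_equal(pack_params(a.params), pack_params(b.params))
        assert a.final_loglik == b.final_loglik


class TestPerNeuron:
    def test_prediction_shapes_and_degenerate_population(self, rng):
        cfg, _, data = small_problem(rng, s3=3, n=40)
        cfg = replace(cfg, n_restarts=2, maxfun=100)
        results = fit_per_neuron(data, cfg)
        assert len(results) == 3
        pred = np.column_stack([r.predict(data.images)[:, 0] for r in results])
        assert pred.shape == data.train_responses.shape
        # with one neuron, the per-neuron condition is the population fit
        data1 = data.subset_neurons([0])
        cfg1 = replace(cfg, s3=1, s2=cfg.hidden_size,
                       rng_seed=cfg.rng_seed + 7919)
        pop1 = fit_multi_restart(data1, cfg1)
        per1 = fit_per_neuron(data1, replace(cfg, s3=1))[0]
        assert np.array_equal(pack_params(pop1.params),
                              pack_params(per1.params))
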