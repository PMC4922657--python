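import numpy as np
import pytest
from hypothesis import given, strategies as st

from poprf import (
    bootstrap_significance,
    evaluate_predictions,
    fev,
    linearize_hsm,
    nli,
    pearson_per_neuron,
    power_decomposition,
)
from poprf.fitting import FitResult
from poprf.model_core import CorticalLayer, DoGParams, HSMParams, dog_kernel


def poisson_validation(rng, v=200, r=10, rate_scale=3.0):
    """One simulated Poisson neuron: (true rates, (v, 1, r) trials)."""
    rates = rate_scale * rng.uniform(0.2, 2.0, size=v)
    trials = rng.poisson(rates[:, None, None], size=(v, 1, r)).astype(float)
    return rates, trials


class TestPearson:
    def test_perfect_and_anticorrelated_predictions(self, rng):
        trials = rng.poisson(2.0, size=(20, 2, 5)).astype(float)
        mean = trials.mean(axis=2)
        assert np.allclose(pearson_per_neuron(mean, trials), 1.0)
        assert np.allclose(pearson_per_neuron(-mean + 10, trials), -1.0)

    def test_matches_longhand_formula(self):
        pred = np.array([[1.0], [3.0], [2.0], [5.0]])
        trials = np.array([[[2.0, 4.0]], [[1.0, 1.0]],
                           [[3.0, 5.0]], [[6.0, 8.0]]])
        x = pred[:, 0]
        y = trials[:, 0].mean(axis=1)
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert pearson_per_neuron(pred, trials)[0] == pytest.approx(expected)

    def test_zero_variance_prediction_flagged_nan(self, rng):
        trials = rng.poisson(2.0, size=(10, 1, 4)).astype(float)
        out = pearson_per_neuron(np.ones((10, 1)), trials)
        assert np.isnan(out[0])

    def test_invariant_to_affine_prediction_rescaling(self, rng):
        trials = rng.poisson(2.0, size=(30, 3, 6)).astype(float)
        pred = rng.uniform(0, 4, size=(30, 3))
        assert np.allclose(pearson_per_neuron(pred, trials),
                           pearson_per_neuron(5.0 * pred + 2.0, trials))


class TestPowerDecomposition:
    def test_identical_trials_have_zero_noise(self, rng):
        one = rng.poisson(2.0, size=(15, 2)).astype(float)
        trials = np.repeat(one[:, :, None], 6, axis=2)
        signal, noise, normalized, clipped = power_decomposition(trials)
        assert np.allclose(noise, 0.0, atol=1e-12)
        assert np.allclose(normalized, 0.0, atol=1e-12)

    def test_no_signal_null_gives_normalized_near_one(self):
        rng = np.random.default_rng(8)
        # stimulus-independent mean: every stimulus has the same rate
        trials = rng.poisson(3.0, size=(200, 3, 10)).astype(float)
        _, _, normalized, _ = power_decomposition(trials)
        assert np.all(normalized >= 0.95)
        assert np.all(normalized <= 1.0)

    def test_scale_invariance_of_normalized_noise(self, rng):
        trials = rng.poisson(2.0, size=(50, 2, 5)).astype(float) \
            + rng.uniform(0, 3, size=(50, 1, 1))
        s1, n1, norm1, _ = power_decomposition(trials)
        s2, n2, norm2, _ = power_decomposition(2.0 * trials)
        assert np.allclose(s2, 4.0 * s1)
        assert np.allclose(n2, 4.0 * n1)
        assert np.allclose(norm2, norm1)

    def test_signal_plus_noise_equals_total(self, rng):
        trials = rng.poisson(2.0, size=(40, 4, 6)).astype(float)
        signal, noise, _, _ = power_decomposition(trials)
        total = np.var(trials, axis=0, ddof=1).mean(axis=1)
        assert np.allclose(signal + noise, total)

    def test_single_trial_rejected(self, rng):
        with pytest.raises(ValueError):
            power_decomposition(rng.poisson(1.0, size=(10, 2, 1)).astype(float))


class TestFev:
    def test_oracle_predictor_approaches_one(self):
        rng = np.random.default_rng(3)
        rates, trials = poisson_validation(rng, v=200, r=50)
        out, included = fev(rates[:, None], trials)
        assert included[0]
        assert 0.9 < out[0] < 1.1

    def test_constant_predictor_near_zero(self):
        rng = np.random.default_rng(3)
        rates, trials = poisson_validation(rng, v=200, r=50)
        grand = np.full((200, 1), trials.mean())
        out, _ = fev(grand, trials)
        assert abs(out[0]) < 0.05

    def test_high_noise_neuron_excluded(self, rng):
        # stimulus-independent rates -> normalized noise power ~ 1 > 0.70
        trials = rng.poisson(3.0, size=(100, 1, 8)).astype(float)
        pred = rng.uniform(1, 5, size=(100, 1))
        _, included = fev(pred, trials)
        assert not included[0]


class TestNli:
    def test_fully_linear_model_scores_zero(self):
        assert nli(0.6, 0.6) == 0.0

    def test_fully_nonlinear_model_scores_one(self):
        assert nli(0.6, -0.2) == 1.0
        assert nli(0.6, 0.0) == 1.0

    def test_linearization_outperforming_model_clamped_to_zero(self):
        assert nli(0.4, 0.5) == 0.0

    def test_nonpositive_model_correlation_clamped_to_zero(self):
        assert nli(0.0, 0.3) == 0.0
        assert nli(-0.2, -0.5) == 0.0

    @given(lc=st.floats(-1, 1), llc=st.floats(-1, 1))
    def test_always_in_unit_interval(self, lc, llc):
        out = float(nli(lc, llc))
        assert 0.0 <= out <= 1.0


class TestLinearizeHsm:
    def test_near_linear_hsm_reproduced_by_linearization(self, near_linear_study):
        s = near_linear_study
        hsm_pred = s["model"].predict(s["val"])[:, 0]
        lin_pred = s["lin"][0].predict(s["val"])
        assert np.corrcoef(hsm_pred, lin_pred)[0, 1] > 0.99

    def test_linearized_kernel_matches_dog_ground_truth(self):
        from conftest import make_near_linear_model
        model = make_near_linear_model(single_dog=True)
        # white noise without per-image standardization keeps the kernel's
        # mean component identifiable (zero-mean stimuli cannot constrain it)
        train = np.random.default_rng(7).standard_normal((20000, 5, 5))
        lin = linearize_hsm(model, train, holdout_seed=0)
        k_hat = lin[0].kernel
        k_true = dog_kernel(model.params.lgn[0], 5).ravel()
        cos = k_hat @ k_true / (np.linalg.norm(k_hat) * np.linalg.norm(k_true))
        assert abs(cos) > 0.9

    def test_deterministic_given_holdout_seed(self, near_linear_study):
        from conftest import make_near_linear_model
        model = make_near_linear_model()
        train = near_linear_study["train"][:2000]
        a = linearize_hsm(model, train, holdout_seed=5)[0]
        b = linearize_hsm(model, train, holdout_seed=5)[0]
        assert np.array_equal(a.kernel, b.kernel)


class TestBootstrap:
    def test_perfect_correlation_significant(self, rng):
        trials = rng.poisson(2.0, size=(50, 1, 8)).astype(float)
        pred = trials.mean(axis=2)
        _, sig = bootstrap_significance(pred, trials, n_boot=200, seed=0)
        assert sig[0]

    def test_null_coverage_near_five_percent(self):
        # independent prediction: the 95% CI should exclude 0 in ~5% of runs
        rng = np.random.default_rng(17)
        hits = 0
        n_runs = 120
        for _ in range(n_runs):
            trials = rng.poisson(2.0, size=(40, 1, 4)).astype(float)
            pred = rng.uniform(0, 1, size=(40, 1))
            _, sig = bootstrap_significance(pred, trials, n_boot=200,
                                            seed=int(rng.integers(2 ** 31)))
            hits += int(sig[0])
        assert 0.005 <= hits / n_runs <= 0.15

    def test_deterministic_given_seed(self, rng):
        trials = rng.poisson(2.0, size=(30, 2, 5)).astype(float)
        pred = rng.uniform(0, 3, size=(30, 2))
        ci_a, _ = bootstrap_significance(pred, trials, n_boot=100, seed=7)
        ci_b, _ = bootstrap_significance(pred, trials, n_boot=100, seed=7)
        assert np.array_equal(ci_a, ci_b)


class TestReport:
    def test_report_assembly_and_summary(self, rng):
        trials = rng.poisson(2.0, size=(50, 3, 8)).astype(float) \
            + rng.uniform(0, 4, size=(50, 1, 1))
        pred = trials.mean(axis=2) + 0.1 * rng.standard_normal((50, 3))
        lin = pred + 0.5 * rng.standard_normal((50, 3))
        report = evaluate_predictions(pred, trials, linearized_pred=lin,
                                      n_boot=100, seed=0)
        df = report.to_dataframe()
        assert len(df) == 3
        assert {"pearson_r", "fev", "nli", "significant"} <= set(df.columns)
        summary = report.summary()
        assert summary["n_neurons"] == 3
        assert np.isfinite(summary["mean_correlation"])
        assert all(0 <= v <= 1 for v in report.nli)
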