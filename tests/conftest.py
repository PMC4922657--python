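import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

from poprf import (
    ModelConfig,
    fit_multi_restart,
    fit_per_neuron,
    fit_rln_population,
    fit_hsm,
    random_init,
)
from poprf.evaluation import pearson_per_neuron
from poprf.synthetic import SyntheticSpec, sample_ground_truth, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def recovery_study():
    """Noiseless response-recovery study: fit a tiny known population.

    Ground truth is an HSM with 2 LGN units, 2 hidden units and 3 neurons;
    500 pink-noise training images; responses equal the generating rates
    (no trial noise).  The fit uses 10 restarts; recovery is judged by the
    correlation of held-out predictions with the true rates (input-output
    recovery — parameters themselves are not identifiable).
    """
    spec = SyntheticSpec(s3=3, s1=2, s2=2, n_train=500, n_val=200, n_trials=2,
                         p=12, target_mean_rate=2.0, seed=3)
    truth, _ = sample_ground_truth(spec)
    dataset, _, val_rates = simulate_dataset(truth, spec, noise="none",
                                             return_rates=True)
    config = ModelConfig(s3=3, s1=2, s2=2, p=12, n_restarts=10, rng_seed=0)
    result = fit_multi_restart(dataset, config)
    pred = result.predict(dataset.val_images)
    pc = pred - pred.mean(axis=0)
    tc = val_rates - val_rates.mean(axis=0)
    r = (pc * tc).sum(0) / np.sqrt((pc ** 2).sum(0) * (tc ** 2).sum(0))
    return {"spec": spec, "truth": truth, "dataset": dataset,
            "config": config, "result": result, "heldout_r": r}


def make_near_linear_model(single_dog: bool = False):
    """An HSM operating entirely in the softplus slope-1 (linear) regime.

    Drives at both layers stay ~3.5 standard deviations above threshold, and
    the output weights cancel the hidden units' threshold offsets, so the
    model's input-output map is linear to a very good approximation while the
    response stays strictly positive with realistic offset-to-signal ratio.
    With ``single_dog`` the first LGN unit feeds straight through, giving a
    neuron whose true linear receptive field is that DoG kernel.
    """
    from poprf.fitting import FitResult
    from poprf.model_core import CorticalLayer, DoGParams, HSMParams

    gain = 0.3
    lgn = [DoGParams(2.0, 2.0, 1.0, 2.0, gain * 8.0, gain * 3.2),
           DoGParams(1.5, 3.0, 0.9, 1.8, gain * 6.4, gain * 1.6)]
    if single_dog:
        hidden = CorticalLayer(np.array([[1.0, 0.0], [1.0, 0.0]]),
                               np.array([-9.0, -9.0]))
        output = CorticalLayer(np.array([[1.0, 0.0]]), np.array([-9.0]))
    else:
        hidden = CorticalLayer(np.array([[0.6, -0.4], [0.3, 0.5]]),
                               np.array([-9.0, -9.0]))
        output = CorticalLayer(np.array([[1.0, -1.0]]), np.array([-11.0]))
    params = HSMParams(lgn=lgn, hidden=hidden, output=output)
    return FitResult(params=params, final_loglik=0.0, train_performance=1.0,
                     seed=0, n_iterations=0, converged=True)


@pytest.fixture(scope="session")
def near_linear_study():
    """Near-linear HSM plus its rLN linearization on pink-noise stimuli."""
    from poprf.evaluation import linearize_hsm

    spec = SyntheticSpec(s3=1, p=5, exponent=1.0, seed=5)
    from poprf.synthetic import generate_images
    rng = np.random.default_rng(5)
    train = generate_images(spec, n_images=60000, rng=rng)
    val = generate_images(spec, n_images=200, rng=rng)
    model = make_near_linear_model()
    lin = linearize_hsm(model, train, holdout_seed=0)
    return {"model": model, "train": train, "val": val, "lin": lin,
            "rng_seed": 5}


@pytest.fixture(scope="session")
def comparison_study():
    """Population vs per-neuron HSM vs rLN on one Poisson synthetic recording.

    Six neurons share three DoG inputs through two hidden units; single-trial
    Poisson training responses and an 8-trial validation set.  The population
    HSM gets 6 restarts; the per-neuron condition gets 1 restart per neuron
    (matched total restart budget).
    """
    spec = SyntheticSpec(s3=6, s1=3, s2=2, n_train=300, n_val=50, n_trials=8,
                         p=12, target_mean_rate=2.0, seed=7)
    truth, _ = sample_ground_truth(spec)
    dataset, _, val_rates = simulate_dataset(truth, spec, return_rates=True)
    config = ModelConfig(s3=6, s1=3, s2=2, p=12, n_restarts=6, rng_seed=0)
    pop = fit_multi_restart(dataset, config)
    pred_pop = pop.predict(dataset.val_images)

    from dataclasses import replace
    per = fit_per_neuron(dataset, replace(config, n_restarts=1))
    pred_sn = np.column_stack([r.predict(dataset.val_images)[:, 0] for r in per])

    rln_models = fit_rln_population(dataset.images, dataset.train_responses,
                                    seed=0)
    pred_rln = np.column_stack([m.predict(dataset.val_images)
                                for m in rln_models])
    return {
        "spec": spec, "truth": truth, "dataset": dataset, "config": config,
        "pop": pop, "per": per, "rln": rln_models, "val_rates": val_rates,
        "pred_pop": pred_pop, "pred_sn": pred_sn, "pred_rln": pred_rln,
        "r_pop": float(np.nanmean(pearson_per_neuron(pred_pop,
                                                     dataset.val_responses))),
        "r_sn": float(np.nanmean(pearson_per_neuron(pred_sn,
                                                    dataset.val_responses))),
        "r_rln": float(np.nanmean(pearson_per_neuron(pred_rln,
                                                     dataset.val_responses))),
    }
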