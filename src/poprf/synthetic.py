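"""Synthetic ground-truth populations, stimuli, and trial data.

Generates everything the rest of the package consumes, with the exact layout
of the experimental data: a stimulus stack of standardized ``p x p`` images,
an ``(n, m)`` single-trial training matrix, and a ``(v, m, r)`` multi-trial
validation tensor.

Stimuli are spectral (pink) noise with radially averaged power proportional
to ``1 / f**exponent`` — a stand-in for natural scenes that reproduces their
second-order statistics (spatial correlation) without copyrighted content.
Ground-truth populations are random HSMs whose neurons share a small pool of
DoG inputs, with a global output gain calibrated so the mean firing rate
matches a target; responses are Poisson draws from the model rates, matching
the fitting likelihood (a Gaussian mode exists to probe misspecification).

Defaults mirror the recording conditions the package targets: 1800 training
images, 50 validation images at 10 trials, a 31x31 grid, 9 LGN units and a
hidden layer of 20% of the neuron count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fitting import Dataset
from .model_core import (
    CorticalLayer,
    DoGParams,
    HSMParams,
    hsm_forward,
)

__all__ = [
    "SyntheticSpec",
    "generate_images",
    "sample_ground_truth",
    "simulate_dataset",
]


@dataclass
class SyntheticSpec:
    """Size and statistics of one synthetic recording.

    ``target_mean_rate`` is in inferred spike counts per image presentation;
    the default of 2.0 is a typical evoked count for a 500 ms natural-image
    presentation in mouse V1 L2/3.  ``exponent`` sets the stimulus power
    spectrum ``1/f**exponent`` (0 = white noise; 1 = default pink noise).
    """

    s3: int = 103
    n_train: int = 1800
    n_val: int = 50
    n_trials: int = 10
    p: int = 31
    s1: int = 9
    s2: int | None = None          # None -> max(1, floor(0.2 * s3))
    exponent: float = 1.0
    target_mean_rate: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("s3", "n_train", "n_val", "n_trials", "p", "s1"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.exponent < 0:
            raise ValueError("exponent must be >= 0")
        if self.target_mean_rate <= 0:
            raise ValueError("target_mean_rate must be > 0")

    @property
    def hidden_size(self) -> int:
        if self.s2 is not None:
            return int(self.s2)
        return max(1, math.floor(0.2 * self.s3))


def generate_images(spec: SyntheticSpec, n_images: int | None = None,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Spectral-noise image stack, standardized per image.

    Each image is white Gaussian noise filtered in the Fourier domain with
    amplitude ``f**(-exponent/2)`` (so power falls as ``1/f**exponent``),
    then shifted/scaled to zero mean and unit variance.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_train if n_images is None else int(n_images)
    p = spec.p
    fx = np.fft.fftfreq(p)[:, None]
    fy = np.fft.fftfreq(p)[None, :]
    f = np.sqrt(fx ** 2 + fy ** 2)
    amp = np.zeros_like(f)
    nonzero = f > 0
    amp[nonzero] = f[nonzero] ** (-spec.exponent / 2.0)
    if spec.exponent == 0:
        amp[:] = 1.0
    amp[0, 0] = 0.0  # mean removed anyway
    white = rng.standard_normal((n, p, p))
    spectra = np.fft.fft2(white) * amp
    images = np.real(np.fft.ifft2(spectra))
    images -= images.mean(axis=(1, 2), keepdims=True)
    sd = images.std(axis=(1, 2), keepdims=True)
    sd[sd == 0] = 1.0
    return images / sd


def sample_ground_truth(spec: SyntheticSpec,
                        rng: np.random.Generator | None = None,
                        max_gain_iter: int = 200
                        ) -> tuple[HSMParams, float]:
    """Draw a random ground-truth population and calibrate its output gain.

    DoG centers fall in the central half of the grid with surrounds 1.5-3x
    wider than centers; each hidden unit is a sparse signed mixture of a few
    LGN units (building oriented, push-pull subunits); output weights are
    non-negative mixtures of hidden units, so the population is genuinely
    nonlinear (complex-cell-like pooling) yet shares its LGN inputs.  The
    scalar gain multiplying the output weights is bisected until the mean
    rate over a calibration image batch is within 10% of
    ``spec.target_mean_rate``.  Returns the calibrated parameters and gain.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    p, s1, s2, s3 = spec.p, spec.s1, spec.hidden_size, spec.s3
    lgn = []
    for _ in range(s1):
        sigma_c = rng.uniform(max(0.8, p / 20.0), p / 6.0)
        sigma_s = min(float(sigma_c * rng.uniform(1.5, 3.0)), float(p))
        lgn.append(DoGParams(
            mu_x=rng.uniform(0.25 * (p - 1), 0.75 * (p - 1)),
            mu_y=rng.uniform(0.25 * (p - 1), 0.75 * (p - 1)),
            sigma_c=float(sigma_c),
            sigma_s=sigma_s,
            alpha=rng.uniform(0.5, 1.5),
            beta=rng.uniform(0.1, 0.8),
        ))
    # sparse signed LGN->hidden mixtures
    wh = np.zeros((s2, s1))
    k_mix = min(s1, 3)
    for i in range(s2):
        picks = rng.choice(s1, size=k_mix, replace=False)
        wh[i, picks] = rng.uniform(0.5, 1.5, size=k_mix) * rng.choice([-1.0, 1.0],
                                                                      size=k_mix)
    th = rng.uniform(0.0, 0.5, size=s2)
    # non-negative hidden->output pooling
    wo = rng.uniform(0.0, 1.0, size=(s3, s2))
    to = rng.uniform(0.5, 1.5, size=s3)

    calib = generate_images(spec, n_images=max(200, spec.n_train // 4),
                            rng=rng)
    target = spec.target_mean_rate

    def mean_rate(gain: float) -> float:
        params = HSMParams(lgn=lgn, hidden=CorticalLayer(wh, th),
                           output=CorticalLayer(gain * wo, to))
        return float(hsm_forward(params, calib).mean())

    # mean rate is monotone increasing in the gain (non-negative output
    # weights onto non-negative hidden activity); bracket then bisect
    lo, hi = 0.0, 1.0
    it = 0
    while mean_rate(hi) < target:
        hi *= 2.0
        it += 1
        if it > max_gain_iter:
            raise RuntimeError("gain calibration failed to bracket the target rate")
    gain = 0.5 * (lo + hi)
    for _ in range(max_gain_iter):
        gain = 0.5 * (lo + hi)
        rate = mean_rate(gain)
        if abs(rate - target) <= 0.02 * target:
            break
        if rate < target:
            lo = gain
        else:
            hi = gain
    if abs(mean_rate(gain) - target) > 0.1 * target:
        raise RuntimeError("gain calibration did not reach the target mean rate")
    params = HSMParams(lgn=lgn, hidden=CorticalLayer(wh, th),
                       output=CorticalLayer(gain * wo, to))
    return params, float(gain)


def simulate_dataset(params: HSMParams, spec: SyntheticSpec,
                     rng: np.random.Generator | None = None,
                     noise: str = "poisson", gaussian_sd: float = 0.5,
                     return_rates: bool = False):
    """Simulate one recording from a ground-truth population.

    Training responses are one noisy draw per stimulus and neuron at the
    model rate; validation responses are ``spec.n_trials`` independent draws
    on a fresh image set.  ``noise`` is ``"poisson"`` (default, matching the
    fitting likelihood), ``"gaussian"`` (additive, clipped at 0) or
    ``"none"`` (responses equal the rates).  With ``return_rates`` the
    underlying training and validation rate matrices are returned as well.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)

    def draw(rates: np.ndarray, shape) -> np.ndarray:
        if noise == "poisson":
            return rng.poisson(np.broadcast_to(rates, shape)).astype(float)
        if noise == "gaussian":
            out = np.broadcast_to(rates, shape) + gaussian_sd * rng.standard_normal(shape)
            return np.clip(out, 0.0, None)
        if noise == "none":
            return np.broadcast_to(rates, shape).copy()
        raise ValueError(f"unknown noise mode {noise!r}")

    images = generate_images(spec, n_images=spec.n_train, rng=rng)
    train_rates = hsm_forward(params, images)
    train = draw(train_rates, train_rates.shape)

    val_images = generate_images(spec, n_images=spec.n_val, rng=rng)
    val_rates = hsm_forward(params, val_images)
    val = draw(val_rates[:, :, None],
               (spec.n_val, params.s3, spec.n_trials))

    dataset = Dataset(images=images, train_responses=train,
                      val_images=val_images, val_responses=val,
                      metadata={"synthetic": True, "seed": spec.seed,
                                "noise": noise})
    if return_rates:
        return dataset, train_rates, val_rates
    return dataset
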