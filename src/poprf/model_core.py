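"""Hierarchical structural model (HSM) architecture and forward pass.

The HSM is a three-layer feed-forward encoding model for a local population
of V1 neurons that share a small pool of LGN-like inputs:

1. An LGN layer of ``s1`` linear difference-of-Gaussians (DoG) kernels applied
   to the stimulus image.
2. A hidden "simple cell" layer of ``s2`` units, each taking a weighted sum of
   LGN outputs through a softplus (logistic-loss) transfer function.
3. An output layer of ``s3`` units — one per recorded neuron — again a
   weighted sum of hidden activities through a softplus.

Each DoG unit ``i`` contributes, at pixel ``(k, l)`` of a ``p x p`` grid,

    K_i(k, l) = (alpha_i / sigma_c_i**2) * exp(-d2 / (2 sigma_c_i**2))
              - (beta_i  / sigma_s_i**2) * exp(-d2 / (2 sigma_s_i**2))

with ``d2 = (k - mu_x_i)**2 + (l - mu_y_i)**2``; its response to an image is
the pixel-wise product summed over the grid.  Each cortical unit applies
``f(x) = log(1 + exp(x - t))`` to its summed drive, with a per-unit threshold
``t``.  The model output is therefore strictly positive, which makes it a
valid Poisson rate for likelihood-based fitting.

Parameters are flat-packed for the optimizer in a fixed canonical order (see
:func:`pack_params`); the total count is ``6*s1 + s2 + s3 + s1*s2 + s2*s3``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "DoGParams",
    "CorticalLayer",
    "HSMParams",
    "ModelConfig",
    "SIGMA_MIN",
    "dog_kernel",
    "lgn_forward",
    "softplus_transfer",
    "hsm_forward",
    "n_params",
    "pack_params",
    "unpack_params",
    "param_bounds",
    "validate_images",
]

#: Lower bound used for DoG widths in bound-constrained optimization.  The
#: model requires strictly positive widths; the optimizer requires a closed
#: interval, so "positive" is realized as ``>= SIGMA_MIN`` (in pixels).
SIGMA_MIN = 1e-2


def validate_images(images: np.ndarray) -> np.ndarray:
    """Validate and coerce an image stack to a float ``(n, p, p)`` array."""
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    if images.ndim != 3 or images.shape[1] != images.shape[2]:
        raise ValueError(f"expected (n, p, p) image stack, got {images.shape}")
    if images.shape[1] < 3:
        raise ValueError("grid side p must be >= 3")
    if not np.all(np.isfinite(images)):
        raise ValueError("image stack contains non-finite values")
    return images


@dataclass(frozen=True)
class DoGParams:
    """Parameters of one LGN unit's difference-of-Gaussians kernel.

    ``mu_x``/``mu_y`` are continuous center coordinates in the 0-based pixel
    frame (``mu_x`` indexes rows, matching the kernel's first axis);
    ``sigma_c``/``sigma_s`` are the center/surround Gaussian widths in
    pixels; ``alpha``/``beta`` are the center/surround weights.  With the
    ``1/sigma**2`` scaling, ``2*pi*alpha`` is approximately the integrated
    mass of the center Gaussian, independent of its width.
    """

    mu_x: float
    mu_y: float
    sigma_c: float
    sigma_s: float
    alpha: float
    beta: float

    def validate(self, p: int) -> None:
        vals = (self.mu_x, self.mu_y, self.sigma_c, self.sigma_s,
                self.alpha, self.beta)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("DoG parameters must be finite")
        if not (0.0 <= self.mu_x <= p - 1 and 0.0 <= self.mu_y <= p - 1):
            raise ValueError(
                f"DoG center ({self.mu_x}, {self.mu_y}) outside image [0, {p - 1}]")
        if not (0.0 < self.sigma_c <= p and 0.0 < self.sigma_s <= p):
            raise ValueError(
                "DoG widths must be positive and not exceed the image side")


@dataclass
class CorticalLayer:
    """One fully connected cortical layer: weights and per-unit thresholds."""

    weights: np.ndarray    # (out_units, in_units)
    thresholds: np.ndarray  # (out_units,)

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.thresholds = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        if self.weights.shape[0] != self.thresholds.shape[0]:
            raise ValueError(
                f"weights {self.weights.shape} and thresholds "
                f"{self.thresholds.shape} disagree on unit count")
        if not (np.all(np.isfinite(self.weights))
                and np.all(np.isfinite(self.thresholds))):
            raise ValueError("cortical layer parameters must be finite")


@dataclass
class HSMParams:
    """Full HSM parameter set: LGN units plus the two cortical layers."""

    lgn: list[DoGParams]
    hidden: CorticalLayer   # (s2, s1)
    output: CorticalLayer   # (s3, s2)

    @property
    def s1(self) -> int:
        return len(self.lgn)

    @property
    def s2(self) -> int:
        return self.hidden.weights.shape[0]

    @property
    def s3(self) -> int:
        return self.output.weights.shape[0]

    def validate(self, p: int) -> None:
        for dog in self.lgn:
            dog.validate(p)
        if self.hidden.weights.shape[1] != self.s1:
            raise ValueError("hidden layer input count must equal s1")
        if self.output.weights.shape[1] != self.s2:
            raise ValueError("output layer input count must equal s2")


@dataclass
class ModelConfig:
    """Model architecture and fitting meta-parameters.

    ``s1`` (number of LGN units) and ``gamma`` (hidden units as a fraction of
    recorded neurons) are the model's two free meta-parameters; performance
    saturates at about ``s1 = 9`` and ``gamma = 0.2``, which are the defaults.
    ``s2`` may be set explicitly to override the ``gamma``-derived size (used
    by the per-neuron fitting condition, which keeps the population's hidden
    layer size).
    """

    s3: int
    s1: int = 9
    gamma: float = 0.2
    s2: int | None = None
    p: int = 31
    n_restarts: int = 50
    rng_seed: int = 0
    maxfun: int = 2000
    ftol: float = 1e-8
    # initialization ranges (uniform), recorded here so sweeps can vary them
    init_sigma_c: tuple[float, float] = (0.5, None)  # None -> p/8
    init_sigma_s: tuple[float, float] = (0.5, None)  # None -> p/2
    init_weight: tuple[float, float] = (-0.1, 0.1)
    init_threshold: tuple[float, float] = (0.0, 1.0)
    init_alpha_beta: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.s1 < 1:
            raise ValueError("s1 must be >= 1")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")
        if self.s3 < 1:
            raise ValueError("s3 must be >= 1")
        if self.p < 3:
            raise ValueError("p must be >= 3")

    @property
    def hidden_size(self) -> int:
        """Effective hidden layer size: explicit ``s2`` or max(1, floor(gamma*s3))."""
        if self.s2 is not None:
            return int(self.s2)
        return max(1, math.floor(self.gamma * self.s3))


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def dog_kernel(dog: DoGParams, p: int) -> np.ndarray:
    """Evaluate one DoG kernel on the discrete ``p x p`` pixel grid."""
    dog.validate(p)
    kk = np.arange(p, dtype=float)[:, None]
    ll = np.arange(p, dtype=float)[None, :]
    d2 = (kk - dog.mu_x) ** 2 + (ll - dog.mu_y) ** 2
    center = (dog.alpha / dog.sigma_c ** 2) * np.exp(-d2 / (2.0 * dog.sigma_c ** 2))
    surround = (dog.beta / dog.sigma_s ** 2) * np.exp(-d2 / (2.0 * dog.sigma_s ** 2))
    return center - surround


def lgn_forward(lgn: Sequence[DoGParams], images: np.ndarray) -> np.ndarray:
    """Responses of the LGN layer: ``(n_images, s1)``, linear in the image."""
    images = validate_images(images)
    p = images.shape[1]
    kernels = np.stack([dog_kernel(d, p).ravel() for d in lgn])  # (s1, p*p)
    return images.reshape(images.shape[0], -1) @ kernels.T


def softplus_transfer(x: np.ndarray | float, t: np.ndarray | float = 0.0) -> np.ndarray:
    """Stable softplus ``log(1 + exp(x - t))``.

    Computed as ``max(0, u) + log1p(exp(-|u|))`` with ``u = x - t`` so the
    result never overflows nor underflows to exactly zero; the output is the
    model's Poisson rate and is later passed through ``log``.
    """
    u = np.asarray(x, dtype=float) - t
    return np.maximum(u, 0.0) + np.log1p(np.exp(-np.abs(u)))


def hsm_forward(params: HSMParams, images: np.ndarray) -> np.ndarray:
    """Predicted firing rates, ``(n_images, s3)``; strictly positive."""
    g1 = lgn_forward(params.lgn, images)
    h = softplus_transfer(g1 @ params.hidden.weights.T, params.hidden.thresholds)
    return softplus_transfer(h @ params.output.weights.T, params.output.thresholds)


# ---------------------------------------------------------------------------
# Flat packing for the optimizer
# ---------------------------------------------------------------------------
# Layout: [per-LGN-unit blocks (mu_x, mu_y, sigma_c, sigma_s, alpha, beta)],
#         hidden weights (row-major), hidden thresholds,
#         output weights (row-major), output thresholds.

def n_params(s1: int, s2: int, s3: int) -> int:
    """Total free-parameter count: ``6*s1 + s2 + s3 + s1*s2 + s2*s3``."""
    return 6 * s1 + s2 + s3 + s1 * s2 + s2 * s3


def pack_params(params: HSMParams) -> np.ndarray:
    """Flatten an :class:`HSMParams` into the canonical parameter vector."""
    lgn_block = np.array(
        [[d.mu_x, d.mu_y, d.sigma_c, d.sigma_s, d.alpha, d.beta]
         for d in params.lgn], dtype=float)
    return np.concatenate([
        lgn_block.ravel(),
        params.hidden.weights.ravel(),
        params.hidden.thresholds,
        params.output.weights.ravel(),
        params.output.thresholds,
    ])


def unpack_params(vector: np.ndarray, config: ModelConfig) -> HSMParams:
    """Inverse of :func:`pack_params` for the shapes implied by ``config``."""
    s1, s2, s3 = config.s1, config.hidden_size, config.s3
    vector = np.asarray(vector, dtype=float)
    expected = n_params(s1, s2, s3)
    if vector.shape != (expected,):
        raise ValueError(
            f"parameter vector has length {vector.shape}, expected ({expected},)")
    i = 0
    lgn_block = vector[i:i + 6 * s1].reshape(s1, 6)
    i += 6 * s1
    wh = vector[i:i + s2 * s1].reshape(s2, s1)
    i += s2 * s1
    th = vector[i:i + s2].copy()
    i += s2
    wo = vector[i:i + s3 * s2].reshape(s3, s2)
    i += s3 * s2
    to = vector[i:i + s3].copy()
    lgn = [DoGParams(*row) for row in lgn_block]
    return HSMParams(lgn=lgn,
                     hidden=CorticalLayer(wh, th),
                     output=CorticalLayer(wo, to))


def param_bounds(config: ModelConfig) -> list[tuple[float | None, float | None]]:
    """Box bounds aligned with :func:`pack_params`.

    Centers are constrained to lie within the image ``[0, p - 1]``; widths to
    ``[SIGMA_MIN, p]``; all other parameters are unbounded.
    """
    s1, s2, s3 = config.s1, config.hidden_size, config.s3
    p = config.p
    per_unit: list[tuple[float | None, float | None]] = [
        (0.0, float(p - 1)), (0.0, float(p - 1)),
        (SIGMA_MIN, float(p)), (SIGMA_MIN, float(p)),
        (None, None), (None, None),
    ]
    bounds = per_unit * s1
    bounds += [(None, None)] * (s2 * s1 + s2 + s3 * s2 + s3)
    return bounds
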