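"""Poisson maximum-likelihood fitting of the HSM.

The objective is the Poisson log-likelihood of the single-trial training
responses given the model's predicted rates,

    log p(y | x, phi) = sum_i y_i * log M(phi, x_i) - sum_i M(phi, x_i)

summed over stimuli and neurons (the ``log y!`` constant is omitted so the
objective is well-defined for the non-integer responses produced by spike
inference).  The objective is maximized by bound-constrained truncated-Newton
optimization (scipy's TNC) with an analytic gradient, restarted from multiple
uniform random initial parameter draws; the restart whose predictions best
correlate with the training responses is selected.  The problem is not
convex and different restarts reach different parameters, but typically
similar input-output functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .model_core import (
    CorticalLayer,
    DoGParams,
    HSMParams,
    ModelConfig,
    SIGMA_MIN,
    hsm_forward,
    lgn_forward,
    n_params,
    pack_params,
    param_bounds,
    softplus_transfer,
    unpack_params,
    validate_images,
)

__all__ = [
    "Dataset",
    "FitResult",
    "poisson_loglik",
    "loglik_gradient",
    "random_init",
    "fit_hsm",
    "fit_multi_restart",
    "fit_per_neuron",
    "mean_pearson",
]


@dataclass
class Dataset:
    """Stimuli and responses in the layout produced by the recording pipeline.

    ``train_responses`` is an ``(n, m)`` matrix of non-negative single-trial
    responses (inferred spike counts, possibly non-integer) of ``m`` neurons
    to ``n`` training images.  ``val_responses`` is a ``(v, m, r)`` tensor of
    responses to ``v`` validation images repeated over ``r`` trials, or
    ``None`` when no validation data exist.
    """

    images: np.ndarray
    train_responses: np.ndarray
    val_images: np.ndarray | None = None
    val_responses: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = validate_images(self.images)
        self.train_responses = np.asarray(self.train_responses, dtype=float)
        if self.train_responses.ndim != 2:
            raise ValueError("train_responses must be (n_stimuli, n_neurons)")
        if self.train_responses.shape[0] != self.images.shape[0]:
            raise ValueError(
                f"train_responses rows ({self.train_responses.shape[0]}) must match "
                f"image count ({self.images.shape[0]})")
        _check_responses(self.train_responses, "train_responses")
        if (self.val_images is None) != (self.val_responses is None):
            raise ValueError("val_images and val_responses must be given together")
        if self.val_images is not None:
            self.val_images = validate_images(self.val_images)
            self.val_responses = np.asarray(self.val_responses, dtype=float)
            if self.val_responses.ndim != 3:
                raise ValueError("val_responses must be (v, n_neurons, n_trials)")
            if self.val_responses.shape[0] != self.val_images.shape[0]:
                raise ValueError("val_responses stimulus count must match val_images")
            if self.val_responses.shape[1] != self.n_neurons:
                raise ValueError(
                    f"val_responses neuron count ({self.val_responses.shape[1]}) must "
                    f"match train_responses ({self.n_neurons})")
            if self.val_images.shape[1] != self.p:
                raise ValueError("train and validation grid sides differ")
            _check_responses(self.val_responses, "val_responses")

    @property
    def n_neurons(self) -> int:
        return self.train_responses.shape[1]

    @property
    def p(self) -> int:
        return self.images.shape[1]

    def subset_neurons(self, idx: Sequence[int]) -> "Dataset":
        idx = list(idx)
        return Dataset(
            images=self.images,
            train_responses=self.train_responses[:, idx],
            val_images=self.val_images,
            val_responses=None if self.val_responses is None
            else self.val_responses[:, idx, :],
            metadata=dict(self.metadata),
        )


def _check_responses(resp: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(resp)):
        raise ValueError(f"{name} contains non-finite values")
    if np.any(resp < 0):
        raise ValueError(f"{name} contains negative values")


@dataclass
class FitResult:
    """Outcome of one (or the best of several) optimization runs."""

    params: HSMParams
    final_loglik: float
    train_performance: float
    seed: int
    n_iterations: int
    converged: bool
    initial_loglik: float = float("nan")
    restarts: list[dict] = field(default_factory=list)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return hsm_forward(self.params, images)


# ---------------------------------------------------------------------------
# Objective and gradient
# ---------------------------------------------------------------------------

def _log_softplus(u: np.ndarray) -> np.ndarray:
    """``log(log(1 + exp(u)))``, stable for large negative drives.

    For ``u`` below about -30, ``softplus(u) = exp(u)`` to machine precision,
    so the log is ``u`` itself; the naive route would underflow to
    ``log(0) = -inf`` near ``u = -745``.
    """
    out = np.where(u < -30.0, u, 0.0)
    safe = u >= -30.0
    sp = softplus_transfer(np.where(safe, u, 0.0))
    return np.where(safe, np.log(sp), out)


def poisson_loglik(params: HSMParams, data: Dataset) -> float:
    """Poisson log-likelihood of the training responses (log y! omitted)."""
    params.validate(data.p)
    g1 = lgn_forward(params.lgn, data.images)
    h = softplus_transfer(g1 @ params.hidden.weights.T, params.hidden.thresholds)
    o_drive = h @ params.output.weights.T - params.output.thresholds
    rates = softplus_transfer(o_drive)
    if rates.shape != data.train_responses.shape:
        raise ValueError(
            f"model output {rates.shape} does not match responses "
            f"{data.train_responses.shape}")
    return float(np.sum(data.train_responses * _log_softplus(o_drive))
                 - np.sum(rates))


def _sigmoid(u: np.ndarray) -> np.ndarray:
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


def _nll_and_grad(x: np.ndarray, config: ModelConfig, images_flat: np.ndarray,
                  y: np.ndarray, p: int) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and its gradient for the packed vector ``x``.

    Hand-derived reverse-mode pass.  The derivative of softplus is the
    logistic sigmoid; the DoG parameters enter only through the kernels, so
    their gradients are inner products of the per-unit image-weighted
    sensitivity map with the analytic kernel partials.
    """
    s1, s2, s3 = config.s1, config.hidden_size, config.s3
    i = 0
    lgn_block = x[i:i + 6 * s1].reshape(s1, 6)
    i += 6 * s1
    wh = x[i:i + s2 * s1].reshape(s2, s1)
    i += s2 * s1
    th = x[i:i + s2]
    i += s2
    wo = x[i:i + s3 * s2].reshape(s3, s2)
    i += s3 * s2
    to = x[i:i + s3]

    kk = np.arange(p, dtype=float)[:, None]
    ll = np.arange(p, dtype=float)[None, :]

    kernels = np.empty((s1, p * p))
    caches = []
    for u in range(s1):
        mu_x, mu_y, sc, ss, alpha, beta = lgn_block[u]
        sc = max(sc, SIGMA_MIN)
        ss = max(ss, SIGMA_MIN)
        dx = kk - mu_x
        dy = ll - mu_y
        d2 = dx ** 2 + dy ** 2
        ec = np.exp(-d2 / (2.0 * sc ** 2))
        es = np.exp(-d2 / (2.0 * ss ** 2))
        kernels[u] = ((alpha / sc ** 2) * ec - (beta / ss ** 2) * es).ravel()
        caches.append((dx, dy, d2, ec, es, sc, ss, alpha, beta))

    g1 = images_flat @ kernels.T                    # (n, s1)
    h_drive = g1 @ wh.T - th                        # (n, s2)
    h = softplus_transfer(h_drive)
    o_drive = h @ wo.T - to                         # (n, s3)
    m = softplus_transfer(o_drive)

    nll = -(np.sum(y * _log_softplus(o_drive)) - np.sum(m))

    # reverse pass (gradients of the *negative* log-likelihood).
    # d(nll)/d(o_drive) = -(y/m - 1) * sigmoid(o_drive); the ratio
    # sigmoid(u)/softplus(u) tends to 1 as u -> -inf, so it is evaluated
    # with an asymptotic branch instead of dividing two underflowing terms.
    sig_o = _sigmoid(o_drive)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ratio = np.where(o_drive < -30.0, 1.0, sig_o / np.where(m > 0, m, 1.0))
    d_odrive = -(y * ratio - sig_o)                 # (n, s3)
    g_wo = d_odrive.T @ h                           # (s3, s2)
    g_to = -d_odrive.sum(axis=0)
    d_h = d_odrive @ wo                             # (n, s2)
    d_hdrive = d_h * _sigmoid(h_drive)
    g_wh = d_hdrive.T @ g1                          # (s2, s1)
    g_th = -d_hdrive.sum(axis=0)
    d_g1 = d_hdrive @ wh                            # (n, s1)
    sens = images_flat.T @ d_g1                     # (p*p, s1): dNLL/dK_u

    g_lgn = np.empty((s1, 6))
    for u in range(s1):
        dx, dy, d2, ec, es, sc, ss, alpha, beta = caches[u]
        G = sens[:, u].reshape(p, p)
        ac = alpha / sc ** 2
        bs = beta / ss ** 2
        g_lgn[u, 0] = np.sum(G * (ac * ec * dx / sc ** 2 - bs * es * dx / ss ** 2))
        g_lgn[u, 1] = np.sum(G * (ac * ec * dy / sc ** 2 - bs * es * dy / ss ** 2))
        g_lgn[u, 2] = np.sum(G * (alpha * ec * (d2 - 2.0 * sc ** 2) / sc ** 5))
        g_lgn[u, 3] = np.sum(G * (-beta * es * (d2 - 2.0 * ss ** 2) / ss ** 5))
        g_lgn[u, 4] = np.sum(G * (ec / sc ** 2))
        g_lgn[u, 5] = np.sum(G * (-es / ss ** 2))

    grad = np.concatenate([g_lgn.ravel(), g_wh.ravel(), g_th,
                           g_wo.ravel(), g_to])
    return nll, grad


def loglik_gradient(params: HSMParams, data: Dataset) -> np.ndarray:
    """Gradient of :func:`poisson_loglik` aligned with :func:`pack_params`."""
    config = ModelConfig(s3=params.s3, s1=params.s1, s2=params.s2, p=data.p)
    x = pack_params(params)
    _, grad = _nll_and_grad(x, config, data.images.reshape(data.images.shape[0], -1),
                            data.train_responses, data.p)
    return -grad


# ---------------------------------------------------------------------------
# Initialization and optimization
# ---------------------------------------------------------------------------

def random_init(config: ModelConfig, rng: np.random.Generator) -> HSMParams:
    """Draw initial parameters uniformly from the configured ranges.

    Centers span the extent of the image; widths, weights and thresholds use
    the configured ranges, all inside the optimizer's box bounds.
    """
    p = config.p
    s1, s2, s3 = config.s1, config.hidden_size, config.s3
    sc_lo, sc_hi = config.init_sigma_c
    ss_lo, ss_hi = config.init_sigma_s
    sc_hi = p / 8.0 if sc_hi is None else sc_hi
    ss_hi = p / 2.0 if ss_hi is None else ss_hi
    ab_lo, ab_hi = config.init_alpha_beta
    w_lo, w_hi = config.init_weight
    t_lo, t_hi = config.init_threshold

    lgn = []
    for _ in range(s1):
        lgn.append(DoGParams(
            mu_x=rng.uniform(0.0, p - 1.0),
            mu_y=rng.uniform(0.0, p - 1.0),
            sigma_c=rng.uniform(sc_lo, sc_hi),
            sigma_s=rng.uniform(ss_lo, ss_hi),
            alpha=rng.uniform(ab_lo, ab_hi),
            beta=rng.uniform(ab_lo, ab_hi),
        ))
    hidden = CorticalLayer(rng.uniform(w_lo, w_hi, size=(s2, s1)),
                           rng.uniform(t_lo, t_hi, size=s2))
    output = CorticalLayer(rng.uniform(w_lo, w_hi, size=(s3, s2)),
                           rng.uniform(t_lo, t_hi, size=s3))
    return HSMParams(lgn=lgn, hidden=hidden, output=output)


def mean_pearson(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean per-neuron Pearson correlation; zero-variance neurons count as 0."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    pc = pred - pred.mean(axis=0)
    tc = target - target.mean(axis=0)
    denom = np.sqrt((pc ** 2).sum(axis=0) * (tc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (pc * tc).sum(axis=0) / denom, 0.0)
    return float(np.mean(r))


def fit_hsm(data: Dataset, config: ModelConfig, init: HSMParams,
            seed: int = 0) -> FitResult:
    """One bound-constrained truncated-Newton run from the given start point."""
    if data.n_neurons != config.s3:
        raise ValueError(
            f"config.s3 ({config.s3}) must equal the neuron count "
            f"({data.n_neurons})")
    if data.p != config.p:
        raise ValueError("config.p must match the dataset grid side")
    init.validate(config.p)
    x0 = pack_params(init)
    images_flat = data.images.reshape(data.images.shape[0], -1)
    y = data.train_responses
    args = (config, images_flat, y, config.p)

    init_ll = -_nll_and_grad(x0, *args)[0]
    res = optimize.minimize(
        _nll_and_grad, x0, args=args, jac=True, method="TNC",
        bounds=param_bounds(config),
        options={"maxfun": config.maxfun, "ftol": config.ftol},
    )
    final_ll = -_nll_and_grad(res.x, *args)[0]
    if final_ll >= init_ll:
        x_best, ll_best, converged = res.x, final_ll, bool(res.success)
    else:  # optimizer returned a worse iterate; keep the start point
        x_best, ll_best, converged = x0, init_ll, False
    params = unpack_params(x_best, config)
    perf = mean_pearson(hsm_forward(params, data.images), y)
    return FitResult(params=params, final_loglik=ll_best,
                     train_performance=perf, seed=seed,
                     n_iterations=int(res.nit), converged=converged,
                     initial_loglik=init_ll)


def fit_multi_restart(data: Dataset, config: ModelConfig,
                      verbose: bool = False) -> FitResult:
    """Fit from ``config.n_restarts`` random starts; keep the best on training.

    Selection uses the mean per-neuron Pearson correlation between the
    predictions and the single-trial training responses; the log-likelihood
    of every restart is recorded alongside.
    """
    if config.n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    master = np.random.SeedSequence(config.rng_seed)
    children = master.spawn(config.n_restarts)
    best: FitResult | None = None
    summaries: list[dict] = []
    failures: list[Exception] = []
    for k, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        init = random_init(config, rng)
        try:
            result = fit_hsm(data, config, init, seed=k)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(exc)
            continue
        summaries.append({
            "seed": k,
            "final_loglik": result.final_loglik,
            "train_performance": result.train_performance,
            "n_iterations": result.n_iterations,
            "converged": result.converged,
        })
        if verbose:
            print(f"restart {k}: loglik={result.final_loglik:.2f} "
                  f"train_r={result.train_performance:.4f} "
                  f"iters={result.n_iterations} converged={result.converged}")
        if best is None or result.train_performance > best.train_performance:
            best = result
    if best is None:
        raise RuntimeError(
            f"all {config.n_restarts} restarts failed; last error: {failures[-1]!r}")
    best.restarts = summaries
    return best


def fit_per_neuron(data: Dataset, config: ModelConfig,
                   verbose: bool = False) -> list[FitResult]:
    """Fit each neuron individually (the single-neuron ablation condition).

    Each neuron is fit as an ``s3 = 1`` model with the same number of LGN
    units and the *population's* hidden layer size, removing only the
    shared-input constraint; used to quantify how much of the population
    model's advantage comes from the shared LGN pool.
    """
    s2 = config.hidden_size
    results = []
    for j in range(data.n_neurons):
        config_j = replace(config, s3=1, s2=s2,
                           rng_seed=config.rng_seed + 7919 * (j + 1))
        results.append(fit_multi_restart(data.subset_neurons([j]), config_j,
                                         verbose=verbose))
    return results
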