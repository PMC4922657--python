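"""Regularized linear-nonlinear (rLN) receptive-field baseline.

The linear stage estimates a pixel-space kernel by Laplacian-regularized
least squares,

    k_hat = pinv(S' S + alpha * L) S' r

where ``S`` is the ``(n, p**2)`` stimulus matrix of flattened images, ``r``
the responses of one neuron, and ``L = D' D`` the squared discrete-Laplacian
penalty, which biases the kernel to be locally smooth rather than small.
The regularization strength ``alpha`` is selected by maximizing the linear
prediction's Pearson correlation on a 10% holdout of the training set, then
the kernel is refit on the full training set.  A point nonlinearity is then
estimated as a histogram fit over 20 equal bins of the filter outputs, and
applied by linear interpolation between the two nearest bin centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import validate_images

__all__ = [
    "PointNonlinearity",
    "RLNModel",
    "build_laplacian_penalty",
    "fit_rln_filter",
    "select_alpha",
    "fit_point_nonlinearity",
    "rln_predict",
    "default_alpha_grid",
    "fit_rln_population",
]


def build_laplacian_penalty(p: int) -> np.ndarray:
    """Squared 5-point Laplacian penalty ``L = D'D`` on the ``p x p`` grid.

    ``D`` uses reduced stencils at borders (no wraparound or ghost pixels):
    each row has ``-deg`` at the center pixel and ``+1`` at each of its
    ``deg`` in-grid neighbors, so constants lie in the null space and ``L``
    is symmetric positive semidefinite.
    """
    if p < 3:
        raise ValueError("p must be >= 3")
    n = p * p
    D = np.zeros((n, n))
    for i in range(p):
        for j in range(p):
            row = i * p + j
            deg = 0
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < p and 0 <= jj < p:
                    D[row, ii * p + jj] = 1.0
                    deg += 1
            D[row, row] = -float(deg)
    return D.T @ D


def fit_rln_filter(S: np.ndarray, L: np.ndarray, r: np.ndarray,
                   alpha_reg: float) -> np.ndarray:
    """Laplacian-regularized kernel estimate ``pinv(S'S + alpha L) S' r``.

    ``r`` may be a length-``n`` vector (one neuron) or an ``(n, m)`` matrix,
    in which case kernels for all ``m`` neurons are returned as columns of a
    ``(p**2, m)`` array, sharing one pseudoinverse.
    """
    S = np.asarray(S, dtype=float)
    L = np.asarray(L, dtype=float)
    r = np.asarray(r, dtype=float)
    if alpha_reg < 0:
        raise ValueError("alpha_reg must be >= 0")
    if S.shape[0] != r.shape[0]:
        raise ValueError("stimulus matrix and responses disagree on n")
    if not (np.all(np.isfinite(S)) and np.all(np.isfinite(r))):
        raise ValueError("non-finite values in design or responses")
    A = S.T @ S + alpha_reg * L
    return np.linalg.pinv(A) @ (S.T @ r)


def default_alpha_grid(S: np.ndarray, n_points: int = 10) -> np.ndarray:
    """Log-spaced grid of regularization strengths, scaled to the design.

    Spans ``1e-2`` to ``1e5`` relative to ``trace(S'S) / p**2``, the average
    per-pixel stimulus energy, so the same grid is sensible across image
    contrasts and training-set sizes.
    """
    scale = np.trace(S.T @ S) / S.shape[1]
    return scale * np.logspace(-2, 5, n_points)


def select_alpha(S: np.ndarray, L: np.ndarray, r: np.ndarray,
                 grid: np.ndarray, holdout_fraction: float = 0.1,
                 seed: int = 0) -> float:
    """Pick the grid alpha maximizing linear-stage correlation on a holdout.

    The split sets aside ``holdout_fraction`` of the training stimuli (seeded
    shuffle, deterministic); for each candidate alpha the kernel is fit on
    the remainder and scored by Pearson correlation of ``S_hold @ k`` with
    the held-out responses.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("alpha grid is empty")
    if grid.size == 1:
        return float(grid[0])
    n = S.shape[0]
    idx = np.random.default_rng(seed).permutation(n)
    n_hold = max(1, int(round(holdout_fraction * n)))
    hold, train = idx[:n_hold], idx[n_hold:]
    r_hold = r[hold]
    if np.std(r_hold) == 0:
        raise ValueError("holdout responses are constant; alpha selection is degenerate")
    best_alpha, best_score = None, -np.inf
    for alpha in grid:
        k = fit_rln_filter(S[train], L, r[train], alpha)
        pred = S[hold] @ k
        if np.std(pred) == 0:
            score = -np.inf
        else:
            score = float(np.corrcoef(pred, r_hold)[0, 1])
        if score > best_score:
            best_alpha, best_score = float(alpha), score
    return best_alpha


@dataclass
class PointNonlinearity:
    """Histogram-estimated point nonlinearity: bin centers and mean outputs."""

    bin_centers: np.ndarray
    bin_values: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.bin_values = np.asarray(self.bin_values, dtype=float)
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        # np.interp interpolates between the two nearest bin centers and
        # clamps queries outside the training range to the edge bin values
        return np.interp(np.asarray(x, dtype=float),
                         self.bin_centers, self.bin_values)


def fit_point_nonlinearity(filter_outputs: np.ndarray, responses: np.ndarray,
                           n_bins: int = 20) -> PointNonlinearity:
    """Histogram fit of the output nonlinearity at ``n_bins`` regular intervals.

    The filter-output range is split into equal bins; each bin's value is the
    mean response of the training points falling in it.  Empty bins are
    filled by linear interpolation between the nearest non-empty neighbors
    (edge gaps take the nearest non-empty value).
    """
    fo = np.asarray(filter_outputs, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if fo.shape != resp.shape or fo.ndim != 1:
        raise ValueError("filter_outputs and responses must be equal-length vectors")
    if fo.size < n_bins:
        raise ValueError(f"need at least {n_bins} samples for {n_bins} bins")
    lo, hi = float(fo.min()), float(fo.max())
    if hi == lo:
        raise ValueError("filter outputs are constant; nonlinearity has no range")
    width = (hi - lo) / n_bins
    which = np.clip(((fo - lo) / width).astype(int), 0, n_bins - 1)
    centers = lo + (np.arange(n_bins) + 0.5) * width
    values = np.full(n_bins, np.nan)
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            values[b] = resp[mask].mean()
    filled = ~np.isnan(values)
    if not filled.all():
        values = np.interp(centers, centers[filled], values[filled])
    return PointNonlinearity(bin_centers=centers, bin_values=values)


@dataclass
class RLNModel:
    """Fitted rLN model for one neuron: linear kernel plus point nonlinearity."""

    kernel: np.ndarray          # length p**2
    alpha_reg: float
    nonlinearity: PointNonlinearity
    p: int = 0

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float).ravel()
        if not self.p:
            self.p = int(round(np.sqrt(self.kernel.size)))
        if self.p * self.p != self.kernel.size:
            raise ValueError("kernel length is not a square")
        if self.alpha_reg < 0:
            raise ValueError("alpha_reg must be >= 0")

    @property
    def kernel_image(self) -> np.ndarray:
        """Kernel reshaped to ``p x p`` for display."""
        return self.kernel.reshape(self.p, self.p)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return rln_predict(self, images)


def rln_predict(model: RLNModel, images: np.ndarray) -> np.ndarray:
    """Predicted responses: kernel projection then interpolated nonlinearity."""
    images = validate_images(images)
    if images.shape[1] != model.p:
        raise ValueError(
            f"image grid side {images.shape[1]} does not match kernel ({model.p})")
    fo = images.reshape(images.shape[0], -1) @ model.kernel
    return model.nonlinearity(fo)


def fit_rln_population(images: np.ndarray, responses: np.ndarray,
                       alpha_grid: np.ndarray | None = None,
                       holdout_fraction: float = 0.1, seed: int = 0,
                       n_bins: int = 20) -> list[RLNModel]:
    """Full rLN pipeline for every neuron of a population.

    Alpha is selected per neuron on one shared seeded 90/10 split; the kernel
    is then refit on the full training set at the selected alpha, and the
    point nonlinearity is estimated on the training set.  Returns one
    :class:`RLNModel` per neuron (column of ``responses``).
    """
    images = validate_images(images)
    responses = np.asarray(responses, dtype=float)
    if responses.ndim == 1:
        responses = responses[:, None]
    if responses.shape[0] != images.shape[0]:
        raise ValueError("responses row count must match the image count")
    p = images.shape[1]
    S = images.reshape(images.shape[0], -1)
    L = build_laplacian_penalty(p)
    if alpha_grid is None:
        alpha_grid = default_alpha_grid(S)
    alpha_grid = np.asarray(alpha_grid, dtype=float)

    m = responses.shape[1]
    # shared split; per-alpha pseudoinverse shared across neurons
    n = S.shape[0]
    idx = np.random.default_rng(seed).permutation(n)
    n_hold = max(1, int(round(holdout_fraction * n)))
    hold, train = idx[:n_hold], idx[n_hold:]
    S_tr, S_ho = S[train], S[hold]
    scores = np.full((alpha_grid.size, m), -np.inf)
    for a_i, alpha in enumerate(alpha_grid):
        K = fit_rln_filter(S_tr, L, responses[train], alpha)  # (p*p, m)
        pred = S_ho @ K
        pc = pred - pred.mean(axis=0)
        rc = responses[hold] - responses[hold].mean(axis=0)
        denom = np.sqrt((pc ** 2).sum(axis=0) * (rc ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            scores[a_i] = np.where(denom > 0, (pc * rc).sum(axis=0) / denom,
                                   -np.inf)
    chosen = alpha_grid[np.argmax(scores, axis=0)]

    models = []
    # refit on the full training set, sharing the pseudoinverse per alpha
    for alpha in np.unique(chosen):
        cols = np.flatnonzero(chosen == alpha)
        K = fit_rln_filter(S, L, responses[:, cols], alpha)
        for c, j in enumerate(cols):
            kernel = K[:, c]
            fo = S @ kernel
            nl = fit_point_nonlinearity(fo, responses[:, j], n_bins=n_bins)
            models.append((j, RLNModel(kernel=kernel, alpha_reg=float(alpha),
                                       nonlinearity=nl, p=p)))
    models.sort(key=lambda t: t[0])
    return [mdl for _, mdl in models]
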