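"""Model evaluation statistics on multi-trial validation data.

Performance is measured on a held-out validation set of ``v`` stimuli with
``r`` repeated trials per neuron:

* **Prediction correlation** — Pearson r between predictions and the
  trial-averaged validation response, per neuron, with a percentile-bootstrap
  significance flag.
* **Signal/noise decomposition** — the across-stimulus variance of a single
  trial splits into stimulus-driven (signal) and trial-to-trial (noise)
  power; the unbiased estimators here use the trial mean's variance with its
  ``noise/r`` inflation removed.  Normalized noise power = noise / total.
* **FEV** — fraction of explained variance,
  ``(signal - (MSE(pred, trial mean) - noise/r)) / signal``, i.e. the share
  of signal power captured after subtracting the noise floor of the
  trial-mean estimate.  Neurons with normalized noise power above 70% are
  flagged for exclusion from FEV summaries (their trial means are too noisy
  for the correction to be reliable).
* **NLI** — the non-linearity index ``(LC - max(LLC, 0)) / LC`` comparing a
  model's validation correlation LC with that of its linearization LLC;
  clamped to 0 when LC < LLC or LC <= 0, so NLI always lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import FitResult
from .rln import RLNModel, fit_rln_population

__all__ = [
    "EvalReport",
    "pearson_per_neuron",
    "power_decomposition",
    "fev",
    "linearize_hsm",
    "nli",
    "bootstrap_significance",
    "evaluate_predictions",
]

NOISE_POWER_EXCLUSION = 0.70


def _check_val(pred: np.ndarray | None, val: np.ndarray) -> np.ndarray:
    val = np.asarray(val, dtype=float)
    if val.ndim != 3:
        raise ValueError("val_responses must be (v, m, r)")
    if pred is not None and np.asarray(pred).shape != val.shape[:2]:
        raise ValueError(
            f"prediction shape {np.asarray(pred).shape} does not match "
            f"validation ({val.shape[0]}, {val.shape[1]})")
    return val


def pearson_per_neuron(pred: np.ndarray, val_responses: np.ndarray) -> np.ndarray:
    """Pearson r of each neuron's prediction against its trial-mean response.

    Neurons with zero-variance prediction or trial mean get NaN (undefined).
    """
    val = _check_val(pred, val_responses)
    if val.shape[0] < 3:
        raise ValueError("need at least 3 validation stimuli")
    pred = np.asarray(pred, dtype=float)
    target = val.mean(axis=2)
    pc = pred - pred.mean(axis=0)
    tc = target - target.mean(axis=0)
    denom = np.sqrt((pc ** 2).sum(axis=0) * (tc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (pc * tc).sum(axis=0) / denom, np.nan)


def power_decomposition(val_responses: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-neuron signal, noise, and normalized noise power.

    Returns ``(signal, noise, normalized, clipped)`` where ``normalized`` is
    clipped to [0, 1] and ``clipped`` flags neurons where clipping occurred
    (or where the total power vanished).  ``signal + noise`` equals the total
    power exactly before clipping.
    """
    val = _check_val(None, val_responses)
    r = val.shape[2]
    if r < 2:
        raise ValueError("power decomposition requires at least 2 trials")
    total = np.var(val, axis=0, ddof=1).mean(axis=1)          # mean over trials
    var_mean = np.var(val.mean(axis=2), axis=0, ddof=1)
    signal = (r * var_mean - total) / (r - 1)
    noise = total - signal
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(total > 0, noise / total, np.nan)
    clipped = (normalized < 0) | (normalized > 1) | ~np.isfinite(normalized)
    normalized = np.clip(normalized, 0.0, 1.0)
    return signal, noise, normalized, clipped


def fev(pred: np.ndarray, val_responses: np.ndarray
        ) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of explained variance with the 70% noise-power exclusion.

    Returns ``(fev, included)``.  FEV is NaN for neurons with non-positive
    signal-power estimates; ``included`` is False for those neurons and for
    neurons whose normalized noise power exceeds 70%.
    """
    val = _check_val(pred, val_responses)
    pred = np.asarray(pred, dtype=float)
    r = val.shape[2]
    signal, noise, normalized, _ = power_decomposition(val)
    trial_mean = val.mean(axis=2)
    mse = ((pred - trial_mean) ** 2).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(signal > 0,
                       (signal - (mse - noise / r)) / signal, np.nan)
    included = (signal > 0) & (normalized <= NOISE_POWER_EXCLUSION)
    return out, included


def linearize_hsm(model: FitResult, images: np.ndarray,
                  alpha_grid: np.ndarray | None = None,
                  holdout_seed: int = 0) -> list[RLNModel]:
    """Linearize a fitted HSM by regressing rLN models onto its predictions.

    The full rLN pipeline (Laplacian-regularized kernel, holdout alpha
    selection, histogram nonlinearity) is run with the HSM's responses to the
    training images substituted for recorded responses, yielding one
    linearized receptive field per modeled neuron.
    """
    hsm_pred = model.predict(images)
    return fit_rln_population(images, hsm_pred, alpha_grid=alpha_grid,
                              seed=holdout_seed)


def nli(lc: np.ndarray | float, llc: np.ndarray | float) -> np.ndarray:
    """Non-linearity index ``(LC - max(LLC, 0)) / LC`` with zero clamps.

    Set to 0 when ``LC < LLC`` (the linearization out-predicts the model) and
    when ``LC <= 0`` (the ratio is meaningless); always in [0, 1].
    """
    lc = np.asarray(lc, dtype=float)
    llc = np.asarray(llc, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (lc - np.maximum(llc, 0.0)) / lc
    out = np.where((lc < llc) | (lc <= 0), 0.0, out)
    return np.clip(out, 0.0, 1.0)


def bootstrap_significance(pred: np.ndarray, val_responses: np.ndarray,
                           n_boot: int = 1000, seed: int = 0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Percentile-bootstrap 95% CI of each neuron's prediction correlation.

    Validation stimuli are resampled with replacement; a neuron's correlation
    is significant iff its CI excludes zero.  Returns ``(ci, significant)``
    with ``ci`` of shape ``(m, 2)``.
    """
    val = _check_val(pred, val_responses)
    if val.shape[0] < 10:
        raise ValueError("bootstrap requires at least 10 validation stimuli")
    pred = np.asarray(pred, dtype=float)
    v, m = pred.shape
    target = val.mean(axis=2)
    rng = np.random.default_rng(seed)
    stats = np.empty((n_boot, m))
    for b in range(n_boot):
        idx = rng.integers(0, v, size=v)
        pb, tb = pred[idx], target[idx]
        pc = pb - pb.mean(axis=0)
        tc = tb - tb.mean(axis=0)
        denom = np.sqrt((pc ** 2).sum(axis=0) * (tc ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            stats[b] = np.where(denom > 0, (pc * tc).sum(axis=0) / denom, np.nan)
    ci = np.nanpercentile(stats, [2.5, 97.5], axis=0).T
    significant = (ci[:, 0] > 0) | (ci[:, 1] < 0)
    return ci, significant


@dataclass
class EvalReport:
    """Per-neuron evaluation statistics for one model on one validation set."""

    pearson_r: np.ndarray
    signal_power: np.ndarray
    noise_power: np.ndarray
    normalized_noise_power: np.ndarray
    noise_power_clipped: np.ndarray
    fev: np.ndarray
    fev_included: np.ndarray
    nli: np.ndarray | None = None
    ci: np.ndarray | None = None
    significant: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            "pearson_r": self.pearson_r,
            "signal_power": self.signal_power,
            "noise_power": self.noise_power,
            "normalized_noise_power": self.normalized_noise_power,
            "noise_power_clipped": self.noise_power_clipped,
            "fev": self.fev,
            "fev_included": self.fev_included,
        }
        if self.nli is not None:
            cols["nli"] = self.nli
        if self.significant is not None:
            cols["ci_low"] = self.ci[:, 0]
            cols["ci_high"] = self.ci[:, 1]
            cols["significant"] = self.significant
        df = pd.DataFrame(cols)
        df.index.name = "neuron"
        return df

    def summary(self) -> dict:
        """Population summary: pooled means/medians and inclusion counts."""
        r = self.pearson_r[np.isfinite(self.pearson_r)]
        incl = self.fev_included.astype(bool)
        out = {
            "n_neurons": int(self.pearson_r.size),
            "mean_correlation": float(np.mean(r)) if r.size else float("nan"),
            "median_correlation": float(np.median(r)) if r.size else float("nan"),
            "mean_fev_included": float(np.mean(self.fev[incl])) if incl.any()
            else float("nan"),
            "n_fev_included": int(incl.sum()),
        }
        if self.nli is not None:
            out["mean_nli"] = float(np.nanmean(self.nli))
        if self.significant is not None:
            out["n_significant"] = int(np.sum(self.significant))
        return out


def evaluate_predictions(pred: np.ndarray, val_responses: np.ndarray,
                         linearized_pred: np.ndarray | None = None,
                         n_boot: int = 1000, seed: int = 0) -> EvalReport:
    """Assemble the full per-neuron evaluation report for a prediction matrix.

    ``linearized_pred``, when given, is the validation prediction of the
    model's linearization and enables the NLI column.
    """
    r = pearson_per_neuron(pred, val_responses)
    signal, noise, normalized, clipped = power_decomposition(val_responses)
    f, included = fev(pred, val_responses)
    report = EvalReport(pearson_r=r, signal_power=signal, noise_power=noise,
                        normalized_noise_power=normalized,
                        noise_power_clipped=clipped, fev=f, fev_included=included)
    if linearized_pred is not None:
        llc = pearson_per_neuron(linearized_pred, val_responses)
        report.nli = nli(r, llc)
    if n_boot > 0:
        report.ci, report.significant = bootstrap_significance(
            pred, val_responses, n_boot=n_boot, seed=seed)
    return report
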